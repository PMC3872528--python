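"""Typed data model, CSV I/O and bundled fixtures for the aggregate source tables.

The audit pipeline consumes four aggregate tables describing a national
insured population aged 40-74, stratified by sex and 5-year age band:

* participation -- population, health-check-eligible and recipient head counts
  (FY2009 administrative report);
* charge_ratio -- per-capita annual medical+pharmaceutical charges of
  health-check recipients vs nonrecipients (FY2008 insurer linkage study);
* benefit_survey -- beneficiary counts and total charges for the whole
  insured population (FY2011 all-claims survey);
* linked_observed -- head counts and per-capita charges of recipients whose
  claims were actually linked in the national claims database (FY2009/FY2010
  hash-key linkage), plus the electronic/paper claim-volume counts used to
  adjust for the database holding electronic claims only.

All monetary values are yen per year; all head counts are persons (the
published population column is printed in thousands and is converted on
load). Printed per-capita and percentage columns are display artifacts:
full-precision values recomputed from counts and totals are authoritative.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import TableSchemaError, TableValidationError

__all__ = [
    "Sex",
    "AGE_BANDS",
    "ALL",
    "StratumKey",
    "key",
    "ParticipationRow",
    "ChargeRatioRow",
    "BenefitSurveyRow",
    "LinkedObservedRow",
    "ClaimVolume",
    "AuditRow",
    "SourceTables",
    "read_table",
    "write_table",
    "read_claim_volume",
    "write_claim_volume",
    "write_audit",
    "read_audit",
    "load_fixtures",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    ALL = "all"


#: The seven 5-year age bands of the source tables (ASCII hyphens).
AGE_BANDS: tuple[str, ...] = (
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74",
)

#: Label of subtotal / grand-total rows.
ALL = "all"

_AGE_ORDER = {band: i for i, band in enumerate(AGE_BANDS)}
_SEX_ORDER = {Sex.MALE: 0, Sex.FEMALE: 1, Sex.ALL: 2}


@dataclass(frozen=True)
class StratumKey:
    """Sex x age-band label identifying one row of every table.

    ``(all, all)`` denotes the grand-total row; ``(sex, all)`` a sex subtotal.
    """

    sex: Sex
    age_band: str

    def __post_init__(self) -> None:
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", Sex(self.sex))
        if self.age_band not in AGE_BANDS and self.age_band != ALL:
            raise TableValidationError(
                f"unknown age band {self.age_band!r}; expected one of "
                f"{AGE_BANDS} or {ALL!r}"
            )

    @property
    def is_total(self) -> bool:
        return self.age_band == ALL or self.sex is Sex.ALL

    def sort_index(self) -> tuple[int, int, int]:
        return (
            1 if self.sex is Sex.ALL else 0,
            _SEX_ORDER[self.sex],
            len(AGE_BANDS) if self.age_band == ALL else _AGE_ORDER[self.age_band],
        )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.sex.value}:{self.age_band}"


def key(sex: Union[Sex, str], age_band: str) -> StratumKey:
    """Coerce ``(sex, age_band)`` to a :class:`StratumKey`."""
    return StratumKey(Sex(sex), age_band)


def _require(cond: bool, row: object, rule: str) -> None:
    if not cond:
        raise TableValidationError(f"invariant violated ({rule}) in row {row!r}")


@dataclass(frozen=True)
class ParticipationRow:
    """Head counts behind the health-check participation rate R = recipients/population."""

    key: StratumKey
    population: int
    eligible: Optional[int]
    recipients: int

    def __post_init__(self) -> None:
        _require(self.population > 0, self, "population > 0")
        _require(0 <= self.recipients <= self.population, self,
                 "0 <= recipients <= population")
        if self.eligible is not None:
            _require(self.recipients <= self.eligible <= self.population, self,
                     "recipients <= eligible <= population")

    @property
    def participation_rate(self) -> float:
        return self.recipients / self.population


@dataclass(frozen=True)
class ChargeRatioRow:
    """Reference per-capita charges of recipients vs nonrecipients; implies r = P(-)/P(+)."""

    key: StratumKey
    percap_recipient: float
    percap_nonrecipient: float

    def __post_init__(self) -> None:
        _require(self.percap_recipient > 0, self, "percap_recipient > 0")
        _require(self.percap_nonrecipient > 0, self, "percap_nonrecipient > 0")

    @property
    def ratio(self) -> float:
        """Unrounded nonrecipient/recipient charge ratio r."""
        return self.percap_nonrecipient / self.percap_recipient


@dataclass(frozen=True)
class BenefitSurveyRow:
    """Beneficiary count and total charges of the whole insured stratum (P = C/N)."""

    key: StratumKey
    beneficiaries: int
    total_charges: float

    def __post_init__(self) -> None:
        _require(self.beneficiaries > 0, self, "beneficiaries > 0")
        _require(self.total_charges >= 0, self, "total_charges >= 0")

    @property
    def percap(self) -> float:
        return self.total_charges / self.beneficiaries


@dataclass(frozen=True)
class LinkedObservedRow:
    """Linked-recipient head count n(+) and per-capita linked charges p(+).

    The observed charges c(+) = n(+) * p(+). ``percap_linked`` is kept at full
    precision so that the product reproduces the published observed-charge
    column to the yen (the published per-capita column is display-rounded).
    """

    key: StratumKey
    linked_recipients: int
    percap_linked: float

    def __post_init__(self) -> None:
        _require(self.linked_recipients >= 0, self, "linked_recipients >= 0")
        _require(self.percap_linked >= 0, self, "percap_linked >= 0")

    @property
    def observed_charges(self) -> float:
        return self.linked_recipients * self.percap_linked


@dataclass(frozen=True)
class ClaimVolume:
    """Electronic vs total claim counts for the medical and pharmacy streams.

    The national claims database holds electronically submitted claims only,
    so observed charges must be inflated by the inverse of the
    computerization rate derived from these counts. A single-stream source
    (e.g. the simulator) may leave one stream at (0, 0); the combined total
    must be positive.
    """

    electronic_medical: int
    total_medical: int
    electronic_pharmacy: int
    total_pharmacy: int

    def __post_init__(self) -> None:
        _require(0 <= self.electronic_medical <= self.total_medical, self,
                 "0 <= electronic_medical <= total_medical")
        _require(0 <= self.electronic_pharmacy <= self.total_pharmacy, self,
                 "0 <= electronic_pharmacy <= total_pharmacy")
        _require(self.total_medical + self.total_pharmacy > 0, self,
                 "combined claim total > 0")


@dataclass(frozen=True)
class AuditRow:
    """One stratum of the observed/expected audit (the machine-readable result table)."""

    key: StratumKey
    recipients: int
    participation_rate: float
    nonrecipient_ratio: float
    percap_all: float
    percap_recipient_est: float
    expected_charges: float
    observed_charges_inflated: float
    linkage_rate: float

    def __post_init__(self) -> None:
        _require(self.recipients >= 0, self, "recipients >= 0")
        _require(self.observed_charges_inflated >= 0, self,
                 "observed_charges_inflated >= 0")


@dataclass(frozen=True)
class SourceTables:
    """The four aggregate source tables plus the claim-volume counts."""

    participation: Mapping[StratumKey, ParticipationRow]
    charge_ratio: Mapping[StratumKey, ChargeRatioRow]
    benefit_survey: Mapping[StratumKey, BenefitSurveyRow]
    linked_observed: Mapping[StratumKey, LinkedObservedRow]
    claim_volume: ClaimVolume

    def strata(self) -> list[StratumKey]:
        """The sex x age strata (totals excluded), in canonical order."""
        keys = [k for k in self.participation if not k.is_total]
        return sorted(keys, key=StratumKey.sort_index)

    def sexes(self) -> list[Sex]:
        seen = {k.sex for k in self.strata()}
        return [s for s in (Sex.MALE, Sex.FEMALE) if s in seen]

    def validate(self) -> None:
        """Cross-table consistency: identical strata; linked <= recipients."""
        base = {k for k in self.participation if not k.is_total}
        for name in ("charge_ratio", "benefit_survey", "linked_observed"):
            other = {k for k in getattr(self, name) if not k.is_total}
            if other != base:
                diff = base.symmetric_difference(other)
                raise TableSchemaError(
                    f"stratum mismatch between participation and {name}: "
                    f"{sorted(str(k) for k in diff)}"
                )
        for k in self.linked_observed:
            if k in self.participation:
                if self.linked_observed[k].linked_recipients > self.participation[k].recipients:
                    raise TableValidationError(
                        f"linked recipients exceed recipients in stratum {k}"
                    )


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

_NUM_CLEAN = re.compile(r"[\s,%]")


def _num(text: object) -> float:
    """Parse a number tolerating space/comma digit grouping and a percent sign."""
    if isinstance(text, (int, float)):
        return float(text)
    s = _NUM_CLEAN.sub("", str(text))
    if s in ("", "nan", "None"):
        return math.nan
    return float(s)


def _int(text: object) -> int:
    v = _num(text)
    if math.isnan(v):
        raise TableValidationError(f"expected an integer, got {text!r}")
    return int(round(v))


def _opt_int(text: object) -> Optional[int]:
    v = _num(text)
    return None if math.isnan(v) else int(round(v))


_SCHEMAS: dict[str, tuple[tuple[str, ...], type]] = {
    "participation": (("sex", "age_band", "population", "eligible", "recipients"),
                      ParticipationRow),
    "charge_ratio": (("sex", "age_band", "percap_recipient", "percap_nonrecipient"),
                     ChargeRatioRow),
    "benefit_survey": (("sex", "age_band", "beneficiaries", "total_charges"),
                       BenefitSurveyRow),
    "linked_observed": (("sex", "age_band", "linked_recipients", "percap_linked"),
                        LinkedObservedRow),
    "audit": (("sex", "age_band", "recipients", "participation_rate",
               "nonrecipient_ratio", "percap_all", "percap_recipient_est",
               "expected_charges", "observed_charges_inflated", "linkage_rate"),
              AuditRow),
}

_CLAIM_VOLUME_COLUMNS = ("electronic_medical", "total_medical",
                         "electronic_pharmacy", "total_pharmacy")


def _row_from_record(schema: str, rec: Mapping[str, object]):
    k = key(str(rec["sex"]).strip(), str(rec["age_band"]).strip())
    if schema == "participation":
        return ParticipationRow(k, _int(rec["population"]),
                                _opt_int(rec.get("eligible", "")),
                                _int(rec["recipients"]))
    if schema == "charge_ratio":
        return ChargeRatioRow(k, _num(rec["percap_recipient"]),
                              _num(rec["percap_nonrecipient"]))
    if schema == "benefit_survey":
        return BenefitSurveyRow(k, _int(rec["beneficiaries"]),
                                _num(rec["total_charges"]))
    if schema == "linked_observed":
        return LinkedObservedRow(k, _int(rec["linked_recipients"]),
                                 _num(rec["percap_linked"]))
    if schema == "audit":
        return AuditRow(k, _int(rec["recipients"]), _num(rec["participation_rate"]),
                        _num(rec["nonrecipient_ratio"]), _num(rec["percap_all"]),
                        _num(rec["percap_recipient_est"]), _num(rec["expected_charges"]),
                        _num(rec["observed_charges_inflated"]), _num(rec["linkage_rate"]))
    raise TableSchemaError(f"unknown table schema {schema!r}")


def read_table(path: Union[str, Path], schema: str) -> list:
    """Read and validate one stratum-keyed CSV table.

    Accepts space/comma digit grouping and percent signs in numeric cells, as
    printed in published tables. Raises :class:`TableSchemaError` on a header
    mismatch or a duplicate stratum, :class:`TableValidationError` when a row
    violates its type's invariants.
    """
    if schema not in _SCHEMAS:
        raise TableSchemaError(f"unknown table schema {schema!r}")
    columns, _ = _SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if tuple(df.columns) != columns:
        raise TableSchemaError(
            f"{path}: header {tuple(df.columns)} does not match {columns}"
        )
    rows = [_row_from_record(schema, rec) for rec in df.to_dict("records")]
    seen: set[StratumKey] = set()
    for r in rows:
        if r.key in seen:
            raise TableSchemaError(f"{path}: duplicate stratum {r.key}")
        seen.add(r.key)
    return rows


def _row_to_record(schema: str, row) -> dict:
    rec = {"sex": row.key.sex.value, "age_band": row.key.age_band}
    for f in dataclasses.fields(row):
        if f.name != "key":
            rec[f.name] = getattr(row, f.name)
    return rec


def write_table(rows: Sequence, path: Union[str, Path], schema: str) -> None:
    """Write a stratum-keyed table as UTF-8 CSV (no thousands separators, '.' decimal)."""
    if schema not in _SCHEMAS:
        raise TableSchemaError(f"unknown table schema {schema!r}")
    columns, _ = _SCHEMAS[schema]
    df = pd.DataFrame([_row_to_record(schema, r) for r in rows], columns=list(columns))
    df.to_csv(path, index=False, float_format="%.12g")


def read_claim_volume(path: Union[str, Path]) -> ClaimVolume:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if tuple(df.columns) != _CLAIM_VOLUME_COLUMNS:
        raise TableSchemaError(
            f"{path}: header {tuple(df.columns)} does not match {_CLAIM_VOLUME_COLUMNS}"
        )
    if len(df) != 1:
        raise TableSchemaError(f"{path}: claim_volume.csv must contain exactly one row")
    rec = df.iloc[0]
    return ClaimVolume(*(_int(rec[c]) for c in _CLAIM_VOLUME_COLUMNS))


def write_claim_volume(volume: ClaimVolume, path: Union[str, Path]) -> None:
    pd.DataFrame([dataclasses.asdict(volume)],
                 columns=list(_CLAIM_VOLUME_COLUMNS)).to_csv(path, index=False)


def write_audit(rows: Sequence[AuditRow], path: Union[str, Path]) -> None:
    """Serialize audit rows in canonical order (strata, sex subtotals, grand total last)."""
    if not rows:
        raise TableValidationError("write_audit requires at least one row")
    ordered = sorted(rows, key=lambda r: r.key.sort_index())
    write_table(ordered, path, "audit")


def read_audit(path: Union[str, Path]) -> list[AuditRow]:
    return read_table(path, "audit")


# ---------------------------------------------------------------------------
# Bundled fixtures: the published aggregate tables, fiscal years 2008-2011.
#
# Populations are printed in thousands and stored here in persons (x1000).
# The per-capita column of the linked-recipient table is display-rounded in
# the publication; percap_linked is therefore stored as observed/n at full
# precision so products reproduce the authoritative observed-charge column.
# The two sex-total observed-charge cells are printed with garbled digit
# grouping in the source; the values below are the column sums of the
# stratum rows and are consistent with the printed grand total
# 716 128 080 857 and with the inflated subtotals of the result table.
# ---------------------------------------------------------------------------

# (age_band, population_thousands, eligible, recipients)
_PARTICIPATION_FIXTURE = {
    Sex.MALE: [
        ("40-44", 4323, 4056351, 2208376),
        ("45-49", 3932, 3685567, 2054324),
        ("50-54", 3863, 3542461, 1903919),
        ("55-59", 4517, 4011840, 1975968),
        ("60-64", 4603, 4078432, 1565725),
        ("65-69", 4005, 3484940, 1214405),
        ("70-74", 3199, 2840267, 1019997),
        (ALL, 28442, 25699858, 11942714),
    ],
    Sex.FEMALE: [
        ("40-44", 4258, 3851465, 1380709),
        ("45-49", 3894, 3552116, 1315061),
        ("50-54", 3877, 3473490, 1293219),
        ("55-59", 4616, 3989531, 1419481),
        ("60-64", 4810, 4375575, 1486006),
        ("65-69", 4380, 3922897, 1481643),
        ("70-74", 3712, 3346803, 1270050),
        (ALL, 29547, 26511877, 9646169),
    ],
}

# (age_band, percap_recipient, percap_nonrecipient) -- yen/person-year
_CHARGE_RATIO_FIXTURE = {
    Sex.MALE: [
        ("40-44", 68460, 83017),
        ("45-49", 89120, 112220),
        ("50-54", 117000, 148787),
        ("55-59", 149394, 197421),
        ("60-64", 191084, 257593),
        ("65-69", 235556, 339828),
        ("70-74", 332376, 512231),
        (ALL, 129273, 188335),
    ],
    Sex.FEMALE: [
        ("40-44", 80391, 93937),
        ("45-49", 92159, 107617),
        ("50-54", 109917, 128035),
        ("55-59", 128347, 154232),
        ("60-64", 158692, 195420),
        ("65-69", 199147, 258205),
        ("70-74", 290377, 403938),
        (ALL, 114226, 147770),
    ],
}

# (age_band, beneficiaries, total_charges_yen)
_BENEFIT_SURVEY_FIXTURE = {
    Sex.MALE: [
        ("40-44", 4006878, 453169049750),
        ("45-49", 3321980, 503331494490),
        ("50-54", 3138226, 624634900530),
        ("55-59", 3465152, 908033409780),
        ("60-64", 4780875, 1650648766370),
        ("65-69", 3459967, 1643229952330),
        ("70-74", 3019459, 1953067625520),
        (ALL, 25192537, 7736115198770),
    ],
    Sex.FEMALE: [
        ("40-44", 3926809, 473955768170),
        ("45-49", 3287134, 491671766320),
        ("50-54", 3139869, 584106152970),
        ("55-59", 3518876, 811274890500),
        ("60-64", 4960455, 1411115393690),
        ("65-69", 3777606, 1421169561630),
        ("70-74", 3483921, 1825207400040),
        (ALL, 26094670, 7018500933320),
    ],
}

# (age_band, linked_recipients, observed_charges_yen)
_LINKED_OBSERVED_FIXTURE = {
    Sex.MALE: [
        ("40-44", 96704, 13943766739),
        ("45-49", 97584, 16699638200),
        ("50-54", 119628, 24674486348),
        ("55-59", 155984, 38308534776),
        ("60-64", 107668, 27248692485),
        ("65-69", 299373, 102421567712),
        ("70-74", 295569, 118534614534),
        (ALL, 1172510, 341831300794),
    ],
    Sex.FEMALE: [
        ("40-44", 89837, 12126810616),
        ("45-49", 94102, 14430862278),
        ("50-54", 120840, 20165611842),
        ("55-59", 163497, 30487271483),
        ("60-64", 241881, 51165276230),
        ("65-69", 424601, 119553750511),
        ("70-74", 378241, 126367197103),
        (ALL, 1512999, 374296780063),
    ],
}

# FY2010 claim counts: electronic/total, medical and pharmacy streams.
_CLAIM_VOLUME_FIXTURE = ClaimVolume(
    electronic_medical=463225000,
    total_medical=503627000,
    electronic_pharmacy=281613000,
    total_pharmacy=281842000,
)


def load_fixtures() -> SourceTables:
    """Return the bundled published aggregate tables as a validated :class:`SourceTables`.

    A fresh object is built on every call, so callers can never corrupt the
    module-level constants.
    """
    participation = {}
    charge_ratio = {}
    benefit_survey = {}
    linked_observed = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        for band, pop_thousands, eligible, recipients in _PARTICIPATION_FIXTURE[sex]:
            k = StratumKey(sex, band)
            participation[k] = ParticipationRow(k, pop_thousands * 1000,
                                                eligible, recipients)
        for band, p_rec, p_non in _CHARGE_RATIO_FIXTURE[sex]:
            k = StratumKey(sex, band)
            charge_ratio[k] = ChargeRatioRow(k, float(p_rec), float(p_non))
        for band, n, c in _BENEFIT_SURVEY_FIXTURE[sex]:
            k = StratumKey(sex, band)
            benefit_survey[k] = BenefitSurveyRow(k, n, float(c))
        for band, n_linked, observed in _LINKED_OBSERVED_FIXTURE[sex]:
            k = StratumKey(sex, band)
            linked_observed[k] = LinkedObservedRow(k, n_linked, observed / n_linked)
    tables = SourceTables(participation, charge_ratio, benefit_survey,
                          linked_observed, _CLAIM_VOLUME_FIXTURE)
    tables.validate()
    return tables
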