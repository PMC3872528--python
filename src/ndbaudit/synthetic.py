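"""Individual-level microsimulator of dual hash-key record linkage.

Emulates the generating process behind the aggregate audit tables: an insured
population in sex x age strata takes an annual health check with a
stratum-specific probability, accrues right-skewed annual medical charges
(recipients and nonrecipients differing by a stratum charge ratio), and
submits claims that are electronic with probability q. Each person carries
two irreversible 32-hex-digit hash keys on each side of the linkage:

* key 1 over (insurer ID, beneficiary ID, date of birth, sex),
* key 2 over (name, date of birth, sex),

and a check-side record links to a claim-side record if either key matches.
Linkage fails when identity fields are rendered inconsistently between the
two sides. Three empirically motivated failure modes are modelled as
independent per-person corruption flags on the claim side:

* name formatting (a space inserted between family and given name on claims
  but not on health-check records) -- breaks key 2;
* date-of-birth calendar (Japanese era vs Gregorian rendering) -- breaks both
  keys, since the date of birth feeds both;
* insurer/beneficiary ID change between the two fiscal years -- breaks key 1.

Hence a person is linkable iff the DOB flag is clear and at least one of the
other two flags is clear, giving the closed-form head-count link probability

    (1 - p_dob) * (1 - p_insurer * p_name).

``aggregate`` regenerates the four aggregate source tables from a simulated
population, so the observed/expected estimator can be validated against the
simulation's known ground truth (``recover``).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import TableValidationError
from .estimator import LinkageEstimate, audit
from .tables import (
    ALL,
    BenefitSurveyRow,
    ChargeRatioRow,
    ClaimVolume,
    LinkedObservedRow,
    ParticipationRow,
    Sex,
    SourceTables,
    StratumKey,
    load_fixtures,
)

logger = logging.getLogger("ndbaudit")

__all__ = [
    "Identity",
    "CorruptionFlags",
    "CorruptionConfig",
    "StratumSpec",
    "SimConfig",
    "SyntheticPerson",
    "SimTruth",
    "default_config",
    "hash_keys",
    "japanese_date",
    "simulate",
    "link",
    "aggregate",
    "RecoveryResult",
    "recover",
]


class Identity(NamedTuple):
    """The identity fields feeding the two hash keys. DOB is an ISO date string."""

    family: str
    given: str
    dob: str
    sex: str
    insurer_id: str
    beneficiary_id: str


class CorruptionFlags(NamedTuple):
    """Per-person claim-side format corruption indicators."""

    name: bool = False
    dob: bool = False
    insurer: bool = False


NO_CORRUPTION = CorruptionFlags(False, False, False)


class CorruptionConfig(BaseModel):
    """Independent per-person probabilities of each claim-side format failure.

    ``per_stratum`` optionally overrides the three probabilities for a
    stratum keyed as ``"<sex>:<age_band>"`` (e.g. ``"male:40-44"``), which
    allows emulating sex/age gradients in linkage failure.
    """

    model_config = ConfigDict(frozen=True)

    p_name_format: float = Field(0.0, ge=0.0, le=1.0)
    p_dob_format: float = Field(0.0, ge=0.0, le=1.0)
    p_insurer_change: float = Field(0.0, ge=0.0, le=1.0)
    per_stratum: Dict[str, "CorruptionConfig"] = Field(default_factory=dict)

    def for_stratum(self, key: StratumKey) -> "CorruptionConfig":
        return self.per_stratum.get(f"{key.sex.value}:{key.age_band}", self)

    def link_probability(self) -> float:
        """Closed-form per-person link probability (1-p_dob)(1-p_ins*p_name)."""
        return (1.0 - self.p_dob_format) * (
            1.0 - self.p_insurer_change * self.p_name_format
        )


class StratumSpec(BaseModel):
    """Simulation parameters of one sex x age stratum."""

    model_config = ConfigDict(frozen=True)

    sex: Sex
    age_band: str
    population: int = Field(ge=0)
    participation: float = Field(ge=0.0, le=1.0)
    percap_recipient_mean: float = Field(gt=0.0)
    nonrecipient_ratio: float = Field(gt=0.0)

    @field_validator("sex")
    @classmethod
    def _no_totals(cls, v: Sex) -> Sex:
        if v is Sex.ALL:
            raise ValueError("stratum sex must be male or female, not 'all'")
        return v

    @property
    def key(self) -> StratumKey:
        return StratumKey(self.sex, self.age_band)


class SimConfig(BaseModel):
    """Full simulator configuration; every source of randomness flows from ``seed``."""

    model_config = ConfigDict(frozen=True)

    strata: List[StratumSpec]
    charge_shape: float = Field(1.5, gt=0.0)
    computerization_prob: float = Field(0.948, gt=0.0, le=1.0)
    zero_spend_prob: float = Field(0.0, ge=0.0, lt=1.0)
    corruption: CorruptionConfig = Field(default_factory=CorruptionConfig)
    seed: int = 0

    @field_validator("strata")
    @classmethod
    def _unique_strata(cls, v: List[StratumSpec]) -> List[StratumSpec]:
        keys = [s.key for s in v]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate strata in config")
        if not v:
            raise ValueError("config must define at least one stratum")
        return v

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


@dataclass(frozen=True)
class SyntheticPerson:
    """One simulated insured person (a row of the population frame)."""

    key: StratumKey
    identity: Identity
    is_recipient: bool
    annual_charges: float
    electronic: bool
    corruption: CorruptionFlags


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated population, by direct enumeration over persons."""

    true_link_rate_charges: float
    true_link_rate_headcount: float
    expected_link_prob_closed_form: float


def default_config(population_per_stratum: int = 15000, seed: int = 12345,
                   corruption: Optional[CorruptionConfig] = None) -> SimConfig:
    """Demo configuration mirroring the published aggregate tables.

    The 14 strata take their participation rates, recipient per-capita means
    and nonrecipient charge ratios from the bundled fixtures; populations are
    scaled down to ``population_per_stratum`` persons. Default corruption
    probabilities (name 0.5, DOB 0.2, insurer 0.5) give a closed-form link
    probability of 0.6; the source audit quantifies no failure rates, so
    these are illustrative magnitudes for the three documented mechanisms.
    """
    fx = load_fixtures()
    if corruption is None:
        corruption = CorruptionConfig(
            p_name_format=0.5, p_dob_format=0.2, p_insurer_change=0.5
        )
    strata = []
    for k in fx.strata():
        part = fx.participation[k]
        cr = fx.charge_ratio[k]
        strata.append(StratumSpec(
            sex=k.sex,
            age_band=k.age_band,
            population=population_per_stratum,
            participation=part.participation_rate,
            percap_recipient_mean=cr.percap_recipient,
            nonrecipient_ratio=cr.ratio,
        ))
    return SimConfig(strata=strata, corruption=corruption, seed=seed)


# ---------------------------------------------------------------------------
# Hash keys
# ---------------------------------------------------------------------------

_ERAS = (  # (first Gregorian year, letter); birth years before 1868 not supported
    (2019, "R"), (1989, "H"), (1926, "S"), (1912, "T"), (1868, "M"),
)


def japanese_date(dob_iso: str) -> str:
    """Render an ISO date in Japanese era notation, e.g. 1965-04-12 -> S40.04.12."""
    year, month, day = (int(p) for p in dob_iso.split("-"))
    for start, letter in _ERAS:
        if year >= start:
            return f"{letter}{year - start + 1}.{month:02d}.{day:02d}"
    raise ValueError(f"unsupported birth year {year}")


def _digest(*fields: str) -> str:
    return hashlib.md5("|".join(fields).encode("utf-8")).hexdigest()


def hash_keys(identity: Identity, side: str = "check",
              flags: CorruptionFlags = NO_CORRUPTION) -> Tuple[str, str]:
    """Compute the two 32-hex-digit keys of one record.

    key 1 digests (insurer ID, beneficiary ID, DOB, sex); key 2 digests
    (name, DOB, sex). On the claim side each set corruption flag alters the
    corresponding field's serialization -- name spacing, DOB calendar, or a
    changed insurer/beneficiary ID -- so the affected key(s) no longer match
    the check side. The digest algorithm is an implementation detail; only
    determinism and collision-freeness matter.
    """
    if side not in ("check", "claim"):
        raise ValueError(f"side must be 'check' or 'claim', not {side!r}")
    if any(not f for f in identity):
        raise TableValidationError(f"empty identity field in {identity!r}")
    name = identity.family + identity.given
    dob = identity.dob
    insurer, beneficiary = identity.insurer_id, identity.beneficiary_id
    if side == "claim":
        if flags.name:
            name = identity.family + " " + identity.given
        if flags.dob:
            dob = japanese_date(identity.dob)
        if flags.insurer:
            insurer = insurer + "#2"
            beneficiary = beneficiary + "#2"
    key1 = _digest(insurer, beneficiary, dob, identity.sex)
    key2 = _digest(name, dob, identity.sex)
    return key1, key2


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_POPULATION_COLUMNS = [
    "person_id", "sex", "age_band", "family", "given", "dob",
    "insurer_id", "beneficiary_id", "is_recipient", "annual_charges",
    "electronic", "corrupt_name", "corrupt_dob", "corrupt_insurer",
    "check_key1", "check_key2", "claim_key1", "claim_key2",
]


def _band_birth_years(age_band: str) -> Tuple[int, int]:
    lo, hi = (int(p) for p in age_band.split("-"))
    # ages are as of the health-check fiscal year (2009)
    return 2009 - hi, 2009 - lo


def simulate(config: SimConfig,
             rng: Optional[np.random.Generator] = None) -> Tuple[pd.DataFrame, SimTruth]:
    """Draw one synthetic population and its linkage ground truth.

    Reproducible given ``config.seed`` (or an explicit ``rng``). Identity
    tokens are synthetic indexed strings: uniqueness, not realism, is what
    the linkage mechanism needs. Charges are gamma-distributed with
    stratum-specific means (``nonrecipient_ratio`` times higher for
    nonrecipients) and common shape; an optional zero-spend mass leaves the
    stratum mean unchanged by rescaling the spenders' mean.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    frames: list[pd.DataFrame] = []
    offset = 0
    for spec in config.strata:
        n = spec.population
        if n == 0:
            continue
        probs = config.corruption.for_stratum(spec.key)
        pid = np.arange(offset, offset + n)
        offset += n
        is_recipient = rng.random(n) < spec.participation
        mean = np.where(is_recipient, spec.percap_recipient_mean,
                        spec.percap_recipient_mean * spec.nonrecipient_ratio)
        shape = config.charge_shape
        charges = rng.gamma(shape, mean / shape)
        if config.zero_spend_prob > 0:
            zero = rng.random(n) < config.zero_spend_prob
            charges = np.where(zero, 0.0, charges / (1.0 - config.zero_spend_prob))
        electronic = rng.random(n) < config.computerization_prob
        c_name = rng.random(n) < probs.p_name_format
        c_dob = rng.random(n) < probs.p_dob_format
        c_ins = rng.random(n) < probs.p_insurer_change

        lo_year, hi_year = _band_birth_years(spec.age_band)
        years = rng.integers(lo_year, hi_year + 1, n)
        months = rng.integers(1, 13, n)
        days = rng.integers(1, 29, n)
        dob = [f"{y}-{m:02d}-{d:02d}" for y, m, d in zip(years, months, days)]

        sex_tok = spec.sex.value
        family = [f"F{i:08d}" for i in pid]
        given = [f"G{i:08d}" for i in pid]
        insurer = [f"I{i % 347:04d}" for i in pid]
        beneficiary = [f"B{i:08d}" for i in pid]

        check1, check2, claim1, claim2 = [], [], [], []
        for i in range(n):
            ident = Identity(family[i], given[i], dob[i], sex_tok,
                             insurer[i], beneficiary[i])
            k1, k2 = hash_keys(ident, "check")
            check1.append(k1)
            check2.append(k2)
            if c_name[i] or c_dob[i] or c_ins[i]:
                flags = CorruptionFlags(bool(c_name[i]), bool(c_dob[i]),
                                        bool(c_ins[i]))
                j1, j2 = hash_keys(ident, "claim", flags)
            else:  # uncorrupted claim-side serialization is identical
                j1, j2 = k1, k2
            claim1.append(j1)
            claim2.append(j2)

        frames.append(pd.DataFrame({
            "person_id": pid,
            "sex": sex_tok,
            "age_band": spec.age_band,
            "family": family,
            "given": given,
            "dob": dob,
            "insurer_id": insurer,
            "beneficiary_id": beneficiary,
            "is_recipient": is_recipient,
            "annual_charges": charges,
            "electronic": electronic,
            "corrupt_name": c_name,
            "corrupt_dob": c_dob,
            "corrupt_insurer": c_ins,
            "check_key1": check1,
            "check_key2": check2,
            "claim_key1": claim1,
            "claim_key2": claim2,
        }))

    if not frames:
        raise TableValidationError("config produced an empty population")
    pop = pd.concat(frames, ignore_index=True)[_POPULATION_COLUMNS]
    return pop, _truth(pop, config)


def _truth(pop: pd.DataFrame, config: SimConfig) -> SimTruth:
    """Ground truth by direct key comparison over persons (electronic restriction excluded)."""
    recip = pop["is_recipient"].to_numpy()
    has_claim = pop["annual_charges"].to_numpy() > 0
    keymatch = (
        (pop["claim_key1"] == pop["check_key1"])
        | (pop["claim_key2"] == pop["check_key2"])
    ).to_numpy() & has_claim
    charges = pop["annual_charges"].to_numpy()
    recip_charges = charges[recip].sum()
    linked_charges = charges[recip & keymatch].sum()
    n_recip = int(recip.sum())
    truth_charges = linked_charges / recip_charges if recip_charges > 0 else float("nan")
    truth_head = keymatch[recip].mean() if n_recip > 0 else float("nan")

    # closed form, expected-recipient-weighted across strata
    weights, probs = [], []
    for spec in config.strata:
        weights.append(spec.population * spec.participation)
        probs.append(config.corruption.for_stratum(spec.key).link_probability())
    w = np.asarray(weights, dtype=float)
    p = np.asarray(probs, dtype=float)
    closed = float((w * p).sum() / w.sum()) if w.sum() > 0 else float("nan")
    return SimTruth(float(truth_charges), float(truth_head), closed)


def to_persons(pop: pd.DataFrame) -> Iterable[SyntheticPerson]:
    """Materialize population rows as :class:`SyntheticPerson` objects (small inputs)."""
    for rec in pop.to_dict("records"):
        yield SyntheticPerson(
            key=StratumKey(Sex(rec["sex"]), rec["age_band"]),
            identity=Identity(rec["family"], rec["given"], rec["dob"],
                              rec["sex"], rec["insurer_id"], rec["beneficiary_id"]),
            is_recipient=bool(rec["is_recipient"]),
            annual_charges=float(rec["annual_charges"]),
            electronic=bool(rec["electronic"]),
            corruption=CorruptionFlags(bool(rec["corrupt_name"]),
                                       bool(rec["corrupt_dob"]),
                                       bool(rec["corrupt_insurer"])),
        )


# ---------------------------------------------------------------------------
# Linkage
# ---------------------------------------------------------------------------

def link(check_records: Iterable[Tuple[object, str, str]],
         claim_records: Iterable[Tuple[object, str, str, bool]]) -> Set[object]:
    """Deterministic dual-key linkage: a check record links iff key 1 OR key 2
    matches any *electronic* claim record (the database holds electronic
    claims only). Returns the set of linked check-record identifiers.
    """
    keys1: Set[str] = set()
    keys2: Set[str] = set()
    for _, k1, k2, electronic in claim_records:
        if electronic:
            keys1.add(k1)
            keys2.add(k2)
    return {rid for rid, k1, k2 in check_records if k1 in keys1 or k2 in keys2}


def link_population(pop: pd.DataFrame) -> Set[int]:
    """Run :func:`link` on a simulated population.

    Check-side records exist for health-check recipients only; claim-side
    records exist for persons with positive annual charges.
    """
    recip = pop[pop["is_recipient"]]
    claims = pop[pop["annual_charges"] > 0]
    return link(
        zip(recip["person_id"], recip["check_key1"], recip["check_key2"]),
        zip(claims["person_id"], claims["claim_key1"], claims["claim_key2"],
            claims["electronic"]),
    )


# ---------------------------------------------------------------------------
# Aggregation back to the source-table schemas
# ---------------------------------------------------------------------------

def _charge_ratio_row(k: StratumKey, group: pd.DataFrame) -> ChargeRatioRow:
    recip_mask = group["is_recipient"]
    mean_rec = group.loc[recip_mask, "annual_charges"].mean()
    mean_non = group.loc[~recip_mask, "annual_charges"].mean()
    if recip_mask.all() or (~recip_mask).all() or not np.isfinite(mean_rec) \
            or not np.isfinite(mean_non) or mean_rec <= 0 or mean_non <= 0:
        # degenerate stratum: one side empty (participation 0 or 1) -- assume
        # equal per-capita charges (ratio 1) rather than fail
        base = group["annual_charges"].mean()
        if not np.isfinite(base) or base <= 0:
            base = 1.0
        logger.warning("degenerate stratum %s: substituting charge ratio 1", k)
        return ChargeRatioRow(k, float(base), float(base))
    return ChargeRatioRow(k, float(mean_rec), float(mean_non))


def _stratum_tables(k: StratumKey, group: pd.DataFrame,
                    linked: Set[int]) -> Tuple[ParticipationRow, ChargeRatioRow,
                                               BenefitSurveyRow, LinkedObservedRow]:
    n = len(group)
    recip = group[group["is_recipient"]]
    part = ParticipationRow(k, n, None, len(recip))
    cr = _charge_ratio_row(k, group)
    bs = BenefitSurveyRow(k, n, float(group["annual_charges"].sum()))
    linked_recip = recip[recip["person_id"].isin(linked)]
    n_linked = len(linked_recip)
    percap = float(linked_recip["annual_charges"].mean()) if n_linked else 0.0
    lo = LinkedObservedRow(k, n_linked, percap)
    return part, cr, bs, lo


def aggregate(pop: pd.DataFrame, linked: Set[int], config: SimConfig) -> SourceTables:
    """Regenerate the four aggregate source tables (plus claim volume) from a
    simulated population and its linked set.

    Emits one row per nonempty stratum and one subtotal row per sex, so the
    output validates under the tables module and supports both audit
    aggregation modes. Empty strata are omitted with a warning. Claims form a
    single stream (the medical columns); the pharmacy columns are zero.
    """
    participation: Dict[StratumKey, ParticipationRow] = {}
    charge_ratio: Dict[StratumKey, ChargeRatioRow] = {}
    benefit_survey: Dict[StratumKey, BenefitSurveyRow] = {}
    linked_observed: Dict[StratumKey, LinkedObservedRow] = {}

    for spec in config.strata:
        k = spec.key
        group = pop[(pop["sex"] == k.sex.value) & (pop["age_band"] == k.age_band)]
        if group.empty:
            logger.warning("empty stratum %s omitted from aggregate tables", k)
            continue
        part, cr, bs, lo = _stratum_tables(k, group, linked)
        participation[k], charge_ratio[k] = part, cr
        benefit_survey[k], linked_observed[k] = bs, lo

    for sex in (Sex.MALE, Sex.FEMALE):
        group = pop[pop["sex"] == sex.value]
        if group.empty:
            continue
        k = StratumKey(sex, ALL)
        part, cr, bs, lo = _stratum_tables(k, group, linked)
        participation[k], charge_ratio[k] = part, cr
        benefit_survey[k], linked_observed[k] = bs, lo

    claims = pop[pop["annual_charges"] > 0]
    volume = ClaimVolume(
        electronic_medical=int(claims["electronic"].sum()),
        total_medical=len(claims),
        electronic_pharmacy=0,
        total_pharmacy=0,
    )
    tables = SourceTables(participation, charge_ratio, benefit_survey,
                          linked_observed, volume)
    tables.validate()
    return tables


# ---------------------------------------------------------------------------
# Recovery harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryResult:
    """Estimated vs true charge-weighted linkage rates over simulation replicates."""

    estimates: Tuple[float, ...]
    truths: Tuple[float, ...]
    mean_error: float
    mean_abs_error: float

    @property
    def errors(self) -> Tuple[float, ...]:
        return tuple(e - t for e, t in zip(self.estimates, self.truths))


def run_pipeline(config: SimConfig,
                 rng: Optional[np.random.Generator] = None,
                 mode: str = "stratum_sum") -> Tuple[LinkageEstimate, SimTruth, SourceTables]:
    """simulate -> link -> aggregate -> audit, returning all three artifacts."""
    pop, truth = simulate(config, rng=rng)
    linked = link_population(pop)
    tables = aggregate(pop, linked, config)
    estimate = audit(tables, mode=mode)
    return estimate, truth, tables


def recover(config: SimConfig, reps: int = 10, mode: str = "stratum_sum") -> RecoveryResult:
    """Validate the estimator against the simulator's ground truth.

    Runs the full pipeline ``reps`` times with seeds derived from
    ``config.seed`` (one spawned child seed sequence per replicate) and
    compares the estimated charge-weighted linkage rate with the true one.
    ``stratum_sum`` aggregation is the default: at stratum level the
    estimator's inputs are exact in-sample aggregates, so recovery is
    unbiased up to Monte-Carlo noise.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(reps)
    estimates, truths = [], []
    for child in children:
        estimate, truth, _ = run_pipeline(config, rng=np.random.default_rng(child),
                                          mode=mode)
        estimates.append(estimate.linkage_rate_charges)
        truths.append(truth.true_link_rate_charges)
    errors = np.asarray(estimates) - np.asarray(truths)
    return RecoveryResult(
        estimates=tuple(estimates),
        truths=tuple(truths),
        mean_error=float(errors.mean()),
        mean_abs_error=float(np.abs(errors).mean()),
    )
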