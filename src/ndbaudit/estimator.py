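"""Observed/expected charge comparison for auditing record-linkage completeness.

The linkage rate of a claims database that joins health-check records to
insurance claims via hash keys is estimated by comparing, per sex x age
stratum:

* **expected charges** ``C(+) = N(+) * P(+)`` of health-check recipients,
  where the recipients' per-capita charge ``P(+)`` is not directly observable
  and is recovered from three aggregate quantities:

  - ``P``  per-capita charges of the whole insured stratum (all-claims survey),
  - ``R``  health-check participation rate ``N(+)/N``,
  - ``r``  the nonrecipient/recipient per-capita charge ratio ``P(-)/P(+)``
    from an external reference linkage (recipients cost less, because
    hospitalized and bedridden persons cannot attend checks).

  Decomposing total charges over recipients and nonrecipients,
  ``P(+)R + P(-)(1-R) = P`` with ``P(-) = r P(+)`` gives

      P(+) = P / (R + r - r*R)

* **observed charges** ``c(+) = sum n(+) p(+)`` actually linked in the
  database, inflated by the inverse of the claims computerization rate ``q``
  because the database holds electronically submitted claims only.

The charge-weighted linkage rate is ``c(+)/q / C(+)``; the head-count rate is
``n(+)/N(+)``. Both are reported: they answer different questions and need
not agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import TableSchemaError
from .tables import (
    ALL,
    AuditRow,
    ClaimVolume,
    LinkedObservedRow,
    Sex,
    SourceTables,
    StratumKey,
)

__all__ = [
    "participation_rate",
    "nonrecipient_ratio",
    "percap_recipient",
    "percap_nonrecipient",
    "expected_charges",
    "ComputerizationRates",
    "computerization_rates",
    "computerization_rate",
    "inflate_observed",
    "observed_charges",
    "linkage_rate_headcount",
    "LinkageEstimate",
    "audit",
    "format_report",
]


def participation_rate(recipients: float, population: float) -> float:
    """Health-check participation rate R = recipients/population, full precision."""
    if population <= 0:
        raise ValueError("population must be positive")
    if not 0 <= recipients <= population:
        raise ValueError("recipients must lie in [0, population]")
    return recipients / population


def nonrecipient_ratio(percap_nonrecipient: float, percap_recipient: float) -> float:
    """Charge ratio r = P(-)/P(+), always recomputed unrounded from the two columns."""
    if percap_nonrecipient <= 0 or percap_recipient <= 0:
        raise ValueError("per-capita charges must be positive")
    return percap_nonrecipient / percap_recipient


def percap_recipient(percap_all: float, participation: float, ratio: float) -> float:
    """Recipients' per-capita charge estimate P(+) = P / (R + r - r*R).

    Satisfies the balance identity ``R*P(+) + (1-R)*r*P(+) = P`` by
    construction. The denominator is positive whenever ``r > 0`` and
    ``0 <= R <= 1``, so the estimate is defined even for degenerate
    participation (R of 0 or 1).
    """
    if percap_all < 0:
        raise ValueError("percap_all must be nonnegative")
    if not 0 <= participation <= 1:
        raise ValueError("participation must lie in [0, 1]")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    denom = participation + ratio - ratio * participation
    if denom <= 0:
        raise ValueError("degenerate denominator R + r - r*R <= 0")
    return percap_all / denom


def percap_nonrecipient(percap_recipient_est: float, ratio: float) -> float:
    """Nonrecipients' per-capita charge P(-) = r * P(+)."""
    if percap_recipient_est <= 0 or ratio <= 0:
        raise ValueError("inputs must be positive")
    return ratio * percap_recipient_est


def expected_charges(recipients: float, percap_recipient_est: float) -> float:
    """Expected total charges C(+) = N(+) * P(+), full precision."""
    if recipients < 0:
        raise ValueError("recipients must be nonnegative")
    return recipients * percap_recipient_est


@dataclass(frozen=True)
class ComputerizationRates:
    """Electronic-claim fractions: per stream and overall (count-weighted)."""

    medical: Optional[float]
    pharmacy: Optional[float]
    overall: float


def computerization_rates(volume: ClaimVolume) -> ComputerizationRates:
    """Electronic/total claim fractions; a stream with zero total yields None."""
    total = volume.total_medical + volume.total_pharmacy
    if total <= 0:
        raise ValueError("claim totals must be positive")
    overall = (volume.electronic_medical + volume.electronic_pharmacy) / total
    medical = (volume.electronic_medical / volume.total_medical
               if volume.total_medical > 0 else None)
    pharmacy = (volume.electronic_pharmacy / volume.total_pharmacy
                if volume.total_pharmacy > 0 else None)
    return ComputerizationRates(medical, pharmacy, overall)


def computerization_rate(volume: ClaimVolume) -> float:
    """Overall claims computerization rate q (count-weighted across streams)."""
    return computerization_rates(volume).overall


def inflate_observed(observed: float, computerization: float) -> float:
    """Adjust observed electronic-claim charges to all-claims scale: observed/q."""
    if not 0 < computerization <= 1:
        raise ValueError("computerization rate must lie in (0, 1]")
    if observed < 0:
        raise ValueError("observed charges must be nonnegative")
    return observed / computerization


def observed_charges(rows: Iterable[LinkedObservedRow]) -> float:
    """Sum of n(+) * p(+) over rows (sub-strata, e.g. by health-guidance status, collapse by summation)."""
    return sum(r.linked_recipients * r.percap_linked for r in rows)


def linkage_rate_headcount(linked: float, recipients: float) -> float:
    """Head-count linkage rate n(+)/N(+)."""
    if recipients <= 0:
        raise ValueError("recipients must be positive")
    if not 0 <= linked <= recipients:
        raise ValueError("linked must lie in [0, recipients]")
    return linked / recipients


@dataclass(frozen=True)
class LinkageEstimate:
    """Full audit result: totals, both linkage rates, and the per-stratum table."""

    observed_total: float
    expected_total: float
    linkage_rate_charges: float
    linkage_rate_headcount: float
    computerization_rate: float
    per_stratum: tuple[AuditRow, ...]

    def row(self, key: StratumKey) -> AuditRow:
        for r in self.per_stratum:
            if r.key == key:
                return r
        raise KeyError(key)


def _stratum_audit_row(tables: SourceTables, k: StratumKey, q: float) -> AuditRow:
    try:
        part = tables.participation[k]
        cr = tables.charge_ratio[k]
        bs = tables.benefit_survey[k]
        lo = tables.linked_observed[k]
    except KeyError as exc:
        raise TableSchemaError(f"stratum {k} missing from a source table") from exc
    R = part.participation_rate
    r = cr.ratio
    P = bs.percap
    p_plus = percap_recipient(P, R, r)
    expected = expected_charges(part.recipients, p_plus)
    inflated = inflate_observed(lo.observed_charges, q)
    rate = inflated / expected if expected > 0 else math.nan
    return AuditRow(
        key=k,
        recipients=part.recipients,
        participation_rate=R,
        nonrecipient_ratio=r,
        percap_all=P,
        percap_recipient_est=p_plus,
        expected_charges=expected,
        observed_charges_inflated=inflated,
        linkage_rate=rate,
    )


def _sum_audit_row(key_: StratumKey, parts: Sequence[AuditRow],
                   population: float, percap_all: float) -> AuditRow:
    """Aggregate audit rows by summing charges; derived columns recomputed."""
    recipients = sum(r.recipients for r in parts)
    expected = sum(r.expected_charges for r in parts)
    inflated = sum(r.observed_charges_inflated for r in parts)
    R = recipients / population if population > 0 else math.nan
    p_plus = expected / recipients if recipients > 0 else math.nan
    # back-solve the ratio implied by the aggregated P(+): r = (P/P(+) - R)/(1 - R)
    if recipients > 0 and p_plus > 0 and R < 1:
        ratio = (percap_all / p_plus - R) / (1 - R)
    else:
        ratio = math.nan
    return AuditRow(
        key=key_,
        recipients=recipients,
        participation_rate=R,
        nonrecipient_ratio=ratio,
        percap_all=percap_all,
        percap_recipient_est=p_plus,
        expected_charges=expected,
        observed_charges_inflated=inflated,
        linkage_rate=inflated / expected if expected > 0 else math.nan,
    )


def audit(
    tables: SourceTables,
    claim_volume: Optional[ClaimVolume] = None,
    mode: str = "paper",
    computerization_precision: Optional[int] = 3,
) -> LinkageEstimate:
    """Run the full observed/expected audit and assemble the result table.

    Parameters
    ----------
    tables
        The four validated source tables (claim volume bundled).
    claim_volume
        Optional override for ``tables.claim_volume``.
    mode
        How subtotal and grand-total rows are aggregated:

        ``"paper"``
            Sex subtotals are computed from the sex-level aggregate inputs
            (the subtotal rows of the source tables), so the aggregate charge
            ratio embeds the sexes' age composition; the grand total is the
            sum of the two sex subtotals. This is the convention of the
            published result table, whose subtotals exceed the sums of their
            stratum rows.
        ``"stratum_sum"``
            Subtotals and the grand total are sums of the stratum-level
            expected and observed charges.
    computerization_precision
        The computerization rate is rounded to this many decimals before
        inflating observed charges (the published audit inflates by the
        inverse of the percent-rounded rate, 0.948). Pass ``None`` to use the
        unrounded rate.

    Returns one :class:`AuditRow` per stratum, one per sex subtotal, and a
    grand-total row last. All intermediates other than the optional
    computerization rounding are carried at full floating precision.
    """
    if mode not in ("paper", "stratum_sum"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    tables.validate()
    volume = claim_volume if claim_volume is not None else tables.claim_volume
    q = computerization_rate(volume)
    if computerization_precision is not None:
        q = round(q, computerization_precision)

    rows: list[AuditRow] = []
    subtotals: list[AuditRow] = []
    strata = tables.strata()
    for sex in tables.sexes():
        sex_rows = [_stratum_audit_row(tables, k, q)
                    for k in strata if k.sex == sex]
        rows.extend(sex_rows)
        sub_key = StratumKey(sex, ALL)
        if mode == "paper":
            if sub_key not in tables.participation:
                raise TableSchemaError(
                    f"mode='paper' requires the {sex.value} subtotal rows in every table"
                )
            sub = _stratum_audit_row(tables, sub_key, q)
        else:
            population = sum(tables.participation[k].population
                             for k in strata if k.sex == sex)
            bene = sum(tables.benefit_survey[k].beneficiaries
                       for k in strata if k.sex == sex)
            charges = sum(tables.benefit_survey[k].total_charges
                          for k in strata if k.sex == sex)
            sub = _sum_audit_row(sub_key, sex_rows, population, charges / bene)
        subtotals.append(sub)
        rows.append(sub)

    # Grand total: the sum of the sex subtotals in both modes (in paper mode
    # the subtotals themselves come from aggregate-level inputs).
    population = sum(tables.participation[k].population for k in strata)
    bene = sum(tables.benefit_survey[k].beneficiaries for k in strata)
    charges = sum(tables.benefit_survey[k].total_charges for k in strata)
    grand = _sum_audit_row(StratumKey(Sex.ALL, ALL), subtotals,
                           population, charges / bene)
    rows.append(grand)

    linked_total = sum(tables.linked_observed[k].linked_recipients for k in strata)
    recipients_total = sum(tables.participation[k].recipients for k in strata)
    return LinkageEstimate(
        observed_total=grand.observed_charges_inflated,
        expected_total=grand.expected_charges,
        linkage_rate_charges=grand.linkage_rate,
        linkage_rate_headcount=linkage_rate_headcount(linked_total, recipients_total),
        computerization_rate=q,
        per_stratum=tuple(rows),
    )


def format_report(estimate: LinkageEstimate) -> str:
    """Plain-text result table mirroring the published layout (percents to 1 decimal)."""
    header = (
        f"{'sex':<7}{'age':<7}{'recipients':>12}{'R':>8}{'r':>7}"
        f"{'P':>10}{'P(+)':>10}{'expected':>18}{'observed(infl.)':>18}{'obs/exp':>9}"
    )
    lines = [
        "Observed and expected charges for health-check recipients",
        f"computerization rate q = {estimate.computerization_rate:.3f} "
        f"(observed charges inflated by 1/q)",
        "",
        header,
        "-" * len(header),
    ]
    for row in estimate.per_stratum:
        lines.append(
            f"{row.key.sex.value:<7}{row.key.age_band:<7}{row.recipients:>12d}"
            f"{row.participation_rate * 100:>7.1f}%{row.nonrecipient_ratio:>7.2f}"
            f"{row.percap_all:>10.0f}{row.percap_recipient_est:>10.0f}"
            f"{row.expected_charges:>18.0f}{row.observed_charges_inflated:>18.0f}"
            f"{row.linkage_rate * 100:>8.1f}%"
        )
    lines += [
        "",
        f"charge-weighted linkage rate: {estimate.linkage_rate_charges * 100:.1f}%",
        f"head-count linkage rate:      {estimate.linkage_rate_headcount * 100:.1f}%",
    ]
    return "\n".join(lines) + "\n"
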