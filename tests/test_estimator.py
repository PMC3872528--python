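"""Estimator formulas against published values and independent oracles."""

import math

import numpy as np
import pytest

from ndbaudit import (
    ClaimVolume,
    LinkedObservedRow,
    Sex,
    SourceTables,
    TableSchemaError,
    audit,
    computerization_rate,
    computerization_rates,
    expected_charges,
    inflate_observed,
    key,
    linkage_rate_headcount,
    nonrecipient_ratio,
    observed_charges,
    participation_rate,
    percap_nonrecipient,
    percap_recipient,
)
from ndbaudit.tables import (
    ALL,
    BenefitSurveyRow,
    ChargeRatioRow,
    ParticipationRow,
    StratumKey,
)


@pytest.mark.parametrize(
    "recipients, population, printed_pct",
    [(11_942_714, 28_442_000, 42.0), (9_646_169, 29_547_000, 32.6)],
)
def test_participation_rate_published(recipients, population, printed_pct):
    assert participation_rate(recipients, population) * 100 == pytest.approx(
        printed_pct, abs=0.05
    )


def test_participation_rate_edges():
    assert participation_rate(0, 1000) == 0.0
    assert participation_rate(1000, 1000) == 1.0
    with pytest.raises(ValueError):
        participation_rate(10, 0)


@pytest.mark.parametrize(
    "non, rec, printed",
    [(83_017, 68_460, 1.21), (188_335, 129_273, 1.46)],
)
def test_nonrecipient_ratio_published(non, rec, printed):
    assert round(nonrecipient_ratio(non, rec), 2) == printed


def test_nonrecipient_ratio_edges():
    assert nonrecipient_ratio(5.0, 5.0) == 1.0
    with pytest.raises(ValueError):
        nonrecipient_ratio(-1.0, 2.0)


def test_percap_recipient_published():
    p_plus = percap_recipient(113_098, 2_208_376 / 4_323_000, 83_017 / 68_460)
    assert p_plus == pytest.approx(102_443, abs=1)


def test_percap_recipient_unit_ratio_identity():
    for R in (0.0, 0.3, 1.0):
        assert percap_recipient(123_456.0, R, 1.0) == pytest.approx(123_456.0)


def test_percap_recipient_linear_system_oracle():
    """Independent check: solve {R*P+ + (1-R)*P- = P, P- = r*P+} numerically."""
    P, R, r = 100_000.0, 0.5, 2.0
    a = np.array([[R, 1 - R], [-r, 1.0]])
    b = np.array([P, 0.0])
    p_plus_oracle, _ = np.linalg.solve(a, b)
    assert percap_recipient(P, R, r) == pytest.approx(p_plus_oracle, rel=1e-12)
    assert p_plus_oracle == pytest.approx(66_666.67, abs=0.01)


def test_percap_nonrecipient_balance_oracle(fixture_tables):
    """P(-) = r*P(+) must agree with (P - R*P(+))/(1-R) on a real stratum."""
    k = key("male", "40-44")
    part = fixture_tables.participation[k]
    cr = fixture_tables.charge_ratio[k]
    P = fixture_tables.benefit_survey[k].percap
    R = part.participation_rate
    r = cr.ratio
    p_plus = percap_recipient(P, R, r)
    oracle = (P - R * p_plus) / (1 - R)
    assert percap_nonrecipient(p_plus, r) == pytest.approx(oracle, rel=1e-9)


def test_percap_nonrecipient_edges():
    assert percap_nonrecipient(7.0, 1.0) == 7.0
    with pytest.raises(ValueError):
        percap_nonrecipient(0.0, 1.2)


def test_expected_charges_published(fixture_tables):
    k = key("male", "40-44")
    p_plus = percap_recipient(
        fixture_tables.benefit_survey[k].percap,
        fixture_tables.participation[k].participation_rate,
        fixture_tables.charge_ratio[k].ratio,
    )
    value = expected_charges(2_208_376, p_plus)
    assert value == pytest.approx(226_231_655_926, rel=1e-4)
    assert expected_charges(0, 12345.0) == 0.0


def test_expected_charges_male_subtotal(fixture_tables):
    k = key("male", ALL)
    p_plus = percap_recipient(
        fixture_tables.benefit_survey[k].percap,
        fixture_tables.participation[k].participation_rate,
        fixture_tables.charge_ratio[k].ratio,
    )
    assert expected_charges(11_942_714, p_plus) == pytest.approx(
        2_899_018_186_819, rel=1e-4
    )


def test_computerization_rates_published(fixture_tables):
    rates = computerization_rates(fixture_tables.claim_volume)
    assert rates.overall * 100 == pytest.approx(94.8, abs=0.05)
    assert rates.medical * 100 == pytest.approx(92.0, abs=0.05)
    assert rates.pharmacy * 100 == pytest.approx(99.9, abs=0.05)


def test_computerization_rate_edges():
    assert computerization_rate(ClaimVolume(5, 5, 7, 7)) == 1.0
    assert computerization_rate(ClaimVolume(1, 2, 1, 2)) == 0.5
    rates = computerization_rates(ClaimVolume(3, 4, 0, 0))
    assert rates.pharmacy is None
    assert rates.overall == 0.75


def test_inflate_observed():
    assert inflate_observed(716_128_080_857, 0.948) == pytest.approx(
        755_409_367_993, abs=1
    )
    assert inflate_observed(42.0, 1.0) == 42.0
    assert inflate_observed(0.0, 0.948) == 0.0
    with pytest.raises(ValueError):
        inflate_observed(1.0, 0.0)


def test_observed_charges_published(fixture_tables):
    row = fixture_tables.linked_observed[key("male", "40-44")]
    assert observed_charges([row]) == pytest.approx(13_943_766_739, abs=row.linked_recipients)


def test_observed_charges_sub_strata_sum():
    k = key("male", "40-44")
    rows = [LinkedObservedRow(k, 10, 100.0), LinkedObservedRow(k, 5, 200.0)]
    assert observed_charges(rows) == 2000.0  # itemized: 10*100 + 5*200
    assert observed_charges([]) == 0.0


@pytest.mark.parametrize(
    "linked, recipients, printed_pct",
    [(1_172_510, 11_942_714, 9.8), (1_512_999, 9_646_169, 15.7)],
)
def test_linkage_rate_headcount_published(linked, recipients, printed_pct):
    assert linkage_rate_headcount(linked, recipients) * 100 == pytest.approx(
        printed_pct, abs=0.05
    )


def test_linkage_rate_headcount_edges():
    assert linkage_rate_headcount(0, 100) == 0.0
    with pytest.raises(ValueError):
        linkage_rate_headcount(1, 0)


# ---------------------------------------------------------------------------
# audit()
# ---------------------------------------------------------------------------

def test_audit_paper_mode_reproduces_published_rates(fixture_tables):
    est = audit(fixture_tables, mode="paper")
    assert est.linkage_rate_charges * 100 == pytest.approx(14.9, abs=0.1)
    assert est.row(key("male", ALL)).linkage_rate * 100 == pytest.approx(12.4, abs=0.1)
    assert est.row(key("female", ALL)).linkage_rate * 100 == pytest.approx(18.2, abs=0.1)
    assert est.row(key("male", "70-74")).linkage_rate * 100 == pytest.approx(25.9, abs=0.1)
    assert len(est.per_stratum) == 17  # 14 strata + 2 subtotals + grand total


def test_audit_row_count_and_order(fixture_tables):
    est = audit(fixture_tables, mode="paper")
    keys = [r.key for r in est.per_stratum]
    assert keys[-1] == StratumKey(Sex.ALL, ALL)
    assert keys[7] == key("male", ALL)
    assert keys[15] == key("female", ALL)


def _self_linked_tables(q=1.0):
    """Tables where observed == expected by construction (r=1, full linkage)."""
    participation, charge_ratio, benefit_survey, linked_observed = {}, {}, {}, {}
    for sex, band, pop, recip, percap in [
        (Sex.MALE, "40-44", 10_000, 4_000, 100_000.0),
        (Sex.FEMALE, "50-54", 8_000, 3_000, 120_000.0),
    ]:
        k = StratumKey(sex, band)
        participation[k] = ParticipationRow(k, pop, None, recip)
        charge_ratio[k] = ChargeRatioRow(k, percap, percap)  # r = 1 -> P(+) = P
        benefit_survey[k] = BenefitSurveyRow(k, pop, pop * percap)
        linked_observed[k] = LinkedObservedRow(k, recip, percap * q)
    volume = ClaimVolume(int(1e6 * q), int(1e6), 0, 0)
    return SourceTables(participation, charge_ratio, benefit_survey,
                        linked_observed, volume)


def test_audit_self_linkage_rates_are_one():
    est = audit(_self_linked_tables(), mode="stratum_sum")
    for row in est.per_stratum:
        assert row.linkage_rate == pytest.approx(1.0, rel=1e-12)


def test_audit_inflation_cancels_electronic_restriction():
    # observed charges thinned to a fraction q, claim volume at the same q:
    # inflation by 1/q restores linkage rate 1 exactly
    est = audit(_self_linked_tables(q=0.9), mode="stratum_sum")
    assert est.linkage_rate_charges == pytest.approx(1.0, rel=1e-9)


def test_audit_mode_discrepancy_is_real(fixture_tables):
    """Aggregate-level r (1.46) exceeds every stratum r, so the published male
    subtotal exceeds the sum of its stratum rows -- an aggregation effect."""
    paper = audit(fixture_tables, mode="paper")
    summed = audit(fixture_tables, mode="stratum_sum")
    male = key("male", ALL)
    assert paper.row(male).expected_charges > summed.row(male).expected_charges
    assert summed.row(male).expected_charges == pytest.approx(
        sum(paper.row(key("male", b)).expected_charges
            for b in ("40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74")),
        rel=1e-12,
    )


def test_audit_stratum_mismatch_raises(fixture_tables):
    broken = SourceTables(
        participation=fixture_tables.participation,
        charge_ratio={k: v for k, v in fixture_tables.charge_ratio.items()
                      if k != key("male", "40-44")},
        benefit_survey=fixture_tables.benefit_survey,
        linked_observed=fixture_tables.linked_observed,
        claim_volume=fixture_tables.claim_volume,
    )
    with pytest.raises(TableSchemaError):
        audit(broken)


def test_audit_headcount_rate(fixture_tables):
    est = audit(fixture_tables)
    assert est.linkage_rate_headcount * 100 == pytest.approx(12.4, abs=0.1)
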