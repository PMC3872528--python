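# Methods

## The audit model

The package audits deterministic record linkage in a claims database that
holds only electronically submitted claims and links health-check records to
claims via two hash keys. Because hashes are irreversible, linkage failure
cannot be diagnosed inside the database; the audit therefore compares

- **observed** charges of linked health-check recipients, `c(+) = Σ n(+)·p(+)`
  (summed over any sub-strata, which collapse by addition), inflated by
  `1/q` where `q` is the claims computerization rate, against
- **expected** charges `C(+) = N(+)·P(+)` of all recipients, with the
  recipients' per-capita charge recovered as

  `P(+) = P / (R + r − r·R)`

  from the population per-capita charge `P = C/N` (all-claims survey), the
  participation rate `R = N(+)/N`, and the nonrecipient/recipient charge
  ratio `r = P(−)/P(+)` taken from an external reference linkage.

The identity behind the estimator is exact bookkeeping, not a statistical
model: total charges split over recipients and nonrecipients as
`P(+)·R + P(−)·(1−R) = P`, and substituting `P(−) = r·P(+)` solves for
`P(+)`. The estimator is therefore exact whenever `R`, `r` and `P` describe
the same population-year. Its real-data assumptions are that the external
ratio `r` (measured on a different insurer population and fiscal year)
transports to the audited population, and that per-capita charges were stable
across the adjacent fiscal years being combined. No uncertainty intervals are
produced: all inputs are administrative aggregates, not samples.

Two linkage rates are reported and deliberately not reconciled: the
charge-weighted rate `(c(+)/q)/C(+)` and the head-count rate `n(+)/N(+)`.
They weight people differently (by spending vs equally) and need not agree.

## Numerical conventions

- All intermediates — `R`, `r`, `P` — are recomputed at full floating
  precision from counts and totals; printed percentage, ratio and per-capita
  columns in the bundled tables are treated as display artifacts. (The
  bundled result values are only reproducible with unrounded inputs, e.g.
  `r = 83 017/68 460`, not the printed 1.21.)
- The one deliberate exception: `audit()` rounds the computerization rate to
  three decimals (0.948272… → 0.948) before inflating observed charges,
  because the published analysis inflates by the inverse of the
  percent-rounded rate and the package reproduces its totals to the yen.
  `computerization_precision=None` disables this.
- The denominator `R + r − r·R` is positive for any `r > 0`, `0 ≤ R ≤ 1`, so
  degenerate participation is well defined; a nonpositive denominator (only
  possible with invalid inputs) raises.
- Aggregation modes: `paper` builds sex subtotals from sex-level aggregate
  inputs and the grand total as the sum of the two subtotals; `stratum_sum`
  sums stratum rows. The two genuinely differ — the aggregate-level `r`
  embeds age composition (the male aggregate ratio 1.46 exceeds every male
  stratum ratio), an instance of aggregation bias — and the discrepancy is
  asserted in the tests, not "fixed". In summed rows the reported ratio
  column is back-solved from the aggregated `P(+)` for display consistency.
- Monetary values are yen throughout; the bundled population column,
  published in thousands, is converted to persons on load. Stratum labels use
  ASCII hyphens in files.

## The microsimulator

`synthetic.simulate` emulates the generating process the audit confronts: an
insured population in 14 sex × age strata; Bernoulli health-check
participation; gamma-distributed annual charges (shape 1.5 by default —
right-skewed and nonnegative; only stratum means matter to the estimator)
with stratum-specific recipient means and a nonrecipient multiplier; a
Bernoulli electronic-claim flag with probability `q`; and per-person,
independent claim-side corruption of identity-field *formatting*:

- name flag — a space inserted between family and given name on the claim
  side (breaks key 2),
- DOB flag — Japanese-era rather than Gregorian rendering of the date of
  birth (breaks both keys, since DOB feeds both),
- insurer flag — a changed insurer/beneficiary ID (breaks key 1).

A person is hence linkable iff the DOB flag is clear and at least one of the
other two is clear, giving the closed-form head-count link probability
`(1 − p_dob)(1 − p_ins·p_name)`, checked in the tests both by truth-table
enumeration of the 8 flag combinations and by Monte-Carlo agreement at
n = 100 000. Corruption applies to all of a person's claims at once (claims
are annualized into one stream per person), matching the mechanism whereby an
ID change corrupts every subsequent hash. The digest is MD5 rendered as 32
hex digits; only determinism and collision-freeness matter, and identity
tokens are synthetic indexed strings, so cross-person collisions cannot
occur. Identity realism (actual Japanese names, true era arithmetic at era
boundaries mid-year) adds nothing to the mechanism and is not attempted.

Defaults in `default_config()`: participation rates, recipient per-capita
means and charge ratios mirror the bundled aggregate tables; `q = 0.948`;
corruption probabilities (name 0.5, DOB 0.2, insurer 0.5) give a link
probability of 0.6. The published analysis quantifies no failure rates —
these are illustrative magnitudes for its three documented failure modes, and
`CorruptionConfig.per_stratum` allows stratum-dependent overrides for
exploring the (unexplained) sex/age gradient as a hypothesis, without taking
a stance on the true cause.

Degenerate strata are tolerated rather than fatal, so property tests can
sweep extremes: a stratum with participation 0 or 1 has no charge ratio, and
`aggregate` substitutes `r = 1` with a logged warning; an empty stratum is
omitted with a warning.

## Recovery validation

`recover` runs simulate → link → aggregate → audit per replicate (seeds
spawned from the config seed via `numpy.random.SeedSequence`) and compares
the estimated charge-weighted linkage rate with the simulation truth (linked
charges over all recipients' charges, by direct key comparison over persons,
*without* the electronic restriction). In `stratum_sum` mode the estimator's
inputs are exact in-sample aggregates, so `P(+)` reproduces the realized
recipient mean exactly and the only stochastic gap is the electronic
thinning, which the `1/q` inflation cancels in expectation — recovery is
unbiased, and with 14 strata × 15 000 persons the mean absolute error over
10 replicates is well under 0.02 (observed ≈ 3·10⁻⁴). A zero-corruption
configuration recovers a rate of 1 for any computerization probability, which
is the cleanest demonstration that the inflation step works.

What passing these tests does **not** show about real data: the simulator
draws `R`, `r` and `P` from the same population the audit sees, so it cannot
detect transport bias in the external ratio `r`, fiscal-year drift, claims
missing for reasons other than computerization, or per-claim (rather than
per-person) corruption — all real possibilities the audit method itself
cannot distinguish from linkage failure.

## Problem sizes and tolerances

The test suite uses 14 × 15 000 persons × 10 replicates for the headline
recovery check and populations of 300–50 000 elsewhere; determinism tests
compare byte-identical CSV output. Reproduction of the bundled result table
is asserted to 0.1 percentage point on rates and 0.01% relative on charge
totals, which absorbs the unknown precision at which the original subtotals
carried their participation rates. Algebraic invariants (the balance
identity, orderings, monotonicity, currency-scale equivariance) are property
tests at 1e-9 relative tolerance, with strict-ordering checks guarded away
from `r ≈ 1` where they degenerate to equalities.

## Known limitations

- The bundled tables contain two cells whose published digit grouping is
  garbled (the sex-total observed charges); the fixtures carry the values
  implied by the column sums, which are consistent with the published grand
  total and the inflated subtotals. The published per-capita column of the
  linked-recipient table is display-rounded; fixtures store `observed/n` at
  full precision.
- The real hash algorithm is undisclosed; MD5 stands in for "any
  deterministic 128-bit digest".
- Claims are simulated as one annualized stream per person; the claim-volume
  table from the simulator therefore fills only one stream.
- No probabilistic/fuzzy linkage is modelled — the audited mechanism is
  exact-key deterministic linkage, and that is what is simulated.
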