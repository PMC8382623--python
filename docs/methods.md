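# Methods

## Model

`stentbim` implements a deterministic budget impact model (BIM) comparing two
treatment scenarios for symptomatic lower-limb peripheral arterial disease
with superficial-femoral-artery lesions: every newly stented patient receives
the Eluvia paclitaxel-eluting stent, versus every patient receiving the
Zilver PTX paclitaxel-coated stent. The budget impact is the difference in
projected costs between the two single-arm scenarios over a six-year horizon
(model years 0–5, calendar 2019–2024 in the shipped base case).

### Population

The annual treated cohort is either (a) a multiplicative funnel — a base
population reduced by a chain of prevalence/eligibility fractions, then by
the endovascular-procedure (EVP) eligibility rate (base 0.80) and the
drug-eluting-stent (DES) use rate (base 0.28) — compounded by an annual
procedure growth rate (~6.8%/yr), or (b) an explicit per-year schedule. The
shipped fixture uses the explicit national schedule
[5674, 6060, 6474, 6915, 7386, 7890] (total 40,399): no single constant
growth rate regenerates it exactly (the implied year-on-year ratios drift
between 1.0680 and 1.0683, consistent with intermediate rounding in the
original spreadsheet model), so the printed row is taken as the input of
record. All cohort arithmetic is unrounded; mortality and attrition are not
modelled.

### Two-cycle event projection

Each annual cohort contributes adverse events for exactly two model cycles
and nothing afterwards. In year *t*, the arm-level counts are

- CD-TLRs: `N_t · r12 + N_{t−1} · r24`
- major amputations: `N_t · a12 + N_{t−1} · a24`
- adverse-event bed-days: `N_t · h12 + N_{t−1} · h24`

with `N_{−1} = 0`. `r12`/`a12` are the exact 12-month trial fractions
(Eluvia CD-TLR 13/287, amputation 1/287; Zilver PTX 13/145 and 0/145);
`r24`/`a24` are the published one-decimal cumulative percentages (12.7%,
1.5%; 20.1%, 0.7%). This mixed convention — fractions at 12 months, printed
percentages at 24 — is the unique combination that reproduces the published
projection cell-by-cell, and is therefore the fixture default.

The default `cumulative_recount` mode applies the full 24-month *cumulative*
rate to the prior cohort, which recounts that cohort's first-year events.
This double-counting is deliberate: it is what the source model demonstrably
does (visible as the marked jump in event rates between the first and second
cycle of each cohort). An `incremental` mode using `r24 − r12` (and
`a24 − a12`) is provided as the epidemiologically cleaner alternative; its
yearly totals are below the cumulative-recount totals by `N_{t−1} · r12`,
so the two modes coincide exactly when `r12 = 0`.

A patient contributes at most one TLR through the rate algebra; there are no
competing risks and no patient-level simulation.

### Bed-day intensity calibration

The per-patient bed-day intensities `h12`, `h24` are not published directly.
They are back-solved from the first two years of published hospital-system
costs divided by the $2,003 per-diem:

    h12 = D0 / N0,    h24 = (D1 − N1·h12) / N0

which exactly inverts the projection's day formula. Calibrating from the
cost cells rather than the rounded day counts keeps two extra significant
digits; the calibrated intensities (Zilver PTX 1.24808 / 2.77830, Eluvia
0.53981 / 2.23600 days/patient) then predict the remaining four years of
published day cells to the nearest day. The trial's summary stay statistics
(13.9/17.7 bed-days per admitted patient; ~19% mean length-of-stay reduction
at 12 months) are carried as metadata with a small helper, but they are not
the source of `h12`/`h24` — no published arithmetic connects them to the
projected day totals.

### Costing and differencing

Two payer perspectives, both in 2019 AUD, no discounting or indexation:

- **Healthcare system** (activity-based funding): per year,
  `N_t·(c_primary + stent_price)` for index procedures, TLRs at the
  cycle-specific percutaneous/open mix priced at $5,495 / $16,411, and
  amputations at $35,354. The index-episode payment `c_primary` is not
  published; it defaults to the percutaneous DRG payment ($5,495) and is
  flagged non-calibrated. It cancels exactly in every between-arm
  difference, so absolute healthcare-cost levels are approximate while the
  savings *structure* (antisymmetry, cohort linearity, invariance to
  `c_primary` and to equal stent prices, monotonicity in comparator rates)
  is exact and is what the test suite asserts. Stent prices default equal
  in both arms (published price difference $0).
- **Hospital**: bed-days × the $2,003 national weighted-average per-diem;
  depends only on the day projection and the per-diem, linearly.

The budget impact is the element-wise comparator-minus-intervention
difference. All arithmetic is unrounded end to end; reports round half away
from zero at display time, and totals are rounded from unrounded sums
(which is why a total can differ by one unit from the sum of its rounded
cells).

### Scenarios and state disaggregation

Every output is homogeneous of degree 1 in the cohort schedule, so
population scenarios (EVP eligibility 0.70–0.99, DES use 0.10–0.40) are run
by rescaling the schedule by `new_rate / base_rate` — provably identical to
re-running the funnel. Stent-price and per-diem scenarios (±5–10%) multiply
the respective costs; the bounds are validated and can be disabled by
config flag. State/territory results scale the national result by each
state's cohort share; the default shares are the published 28%-DES-use state
cohorts divided by the national 40,399 (they sum to 0.984 — about 1.6% of
the national cohort is unallocated in the source, and shares are not forced
to total 1).

## Synthetic data

The generator emulates the statistical structure the analysis assumes: a
two-arm trial with binomial 12-month event counts and cumulative 24-month
counts (extra events drawn among the still event-free at the conditional
excess rate, so counts are monotone and the marginal 24-month rate is
honoured), multinomial procedure-mix draws, and per-year bed-day totals with
zero-truncated Gaussian noise (day totals are continuous derived quantities,
not admission counts). Each generator draws from its own named substream of
a single integer seed, so adding a generator never perturbs existing
streams. What the generator does **not** emulate: between-centre
heterogeneity, time-varying rates within a cycle, censoring, or correlation
between event types — so passing recovery tests demonstrates the engine's
algebra and the calibration's statistical behaviour, not robustness to those
real-data features.

Calibration recovery is validated at cohort sizes near the base case
(N₀ ≈ 5,674) with day-noise standard deviation 50 over 200 replicate seeds
(Monte-Carlo standard error ≈ 50/(5674·√200) ≈ 6×10⁻⁵ days/patient), and
exactly in the noise-free case. These sizes keep the whole property suite
within seconds while leaving the sampling error an order of magnitude below
the asserted 0.01-day tolerance.

## Numerical choices

- Display rounding is half away from zero (`floor(|x| + 0.5)`), applied
  only in `reporting`; the engine never rounds.
- Arm-level invariants (rates in [0,1], mixes summing to 1 within 1e-9,
  cumulative rates non-decreasing) are enforced at config validation, for
  both projection modes — the incremental mode would otherwise produce
  negative second-cycle counts.
- Calibration raises on `N0 = 0` and warns (rather than fails) when the
  implied `h24` is negative, since inconsistent observed inputs are a data
  problem, not a programming error.
- Procedure-mix splits preserve totals exactly by construction
  (`perc + open = tlr` identically).

## Known limitations

- Absolute healthcare-system cost levels (and hence the absolute
  healthcare-savings figures) depend on unpublished DRG cost weights for
  the index episode; only their differences and structural properties are
  reproducible, and the package flags `c_primary` accordingly.
- Single-country (AUD), no private-insurance perspective, no discounting,
  no projections beyond 24 months per cohort, no mortality.
- The state disaggregation assumes a uniform national DES-use rate across
  states; the source does not state otherwise.
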