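# Methods

## Model structure

`strokecea` implements a two-stage cohort model comparing stent-retriever
mechanical thrombectomy plus best medical management (SR+BMM) against best
medical management alone (BMM) in basilar artery occlusion, from a
healthcare-system perspective (direct medical costs only, 2021 USD).

**Stage 1 — decision tree (0–90 days).** Each strategy is expanded as an
expected value over its 90-day modified-Rankin-Scale outcome distribution:
non-disabling (mRS 0–2), disabling (mRS 3–5), dead (mRS 6). The arm cost is

```
cost = [device cost, SR arm only]
     + P(IVT) x IVT cost + P(sICH) x sICH cost
     + Σ_state P(state) x acute management cost(state)
```

IVT (intravenous thrombolysis) and sICH (symptomatic intracranial
hemorrhage) enter as expected *cost* terms only: the 90-day outcome
distributions already contain every trial event, so pricing them separately
must not move outcome mass. Patients dying within the first 90 days accrue
the acute death cost and zero QALY/LY for the whole first cycle; survivors
accrue the full 0.25-year state utility. The tree occupies the model's
first quarter-year and is undiscounted (discount factor 1 at t = 0).

**Stage 2 — Markov cohort model (90 days to 20 years).** Five states:
non-disabling, disabling, two one-cycle recurrent-stroke *tunnel* states
keyed by origin, and absorbing death. The tunnel split encodes the clinical
assumption that a recurrence after a disabling stroke cannot exit to the
non-disabling state, which a memoryless four-state chain cannot represent.
Quarterly cycles (79 of them by default); transition rows come in two eras
(months 3–12 versus after year 1). Recurrent-stroke mass from each living
state is routed into the origin-matched tunnel.

**Background mortality.** Age-banded annual all-cause mortality (5-year
bands, 60–64 through 85+; ages beyond the table use the terminal band) is
converted to a quarterly probability by `1 − (1 − p)^0.25` (the compound
form and the rate form `1 − exp(−r/4)` differ by under 1e−4 at these
magnitudes) and layered onto each living row as an independent competing
risk:

```
p_die = 1 − (1 − p_row_death) (1 − p_background x RR)
```

with the added death mass removed proportionally from the non-death
entries. The relative risk of non-stroke death (1.68) applies only to
occupants of the disabling and recurrent-from-disabling states, matching
its mRS 3–5 provenance. How stroke-specific row deaths and a life table
interact is a structural choice no printed table resolves, so the engine
exposes `background_mortality_mode`:

* `compose` (default) — the multiplicative competing-risk form above;
* `ignore` — row deaths only;
* `replace_if_larger` — `max(p_row_death, p_background x RR)`.

`compose` is the default because it reproduces the published base-case
totals far more closely than the alternatives (all eight within ~1% versus
3–10%); the acceptance harness sweeps all three.

**Accrual and discounting.** Cycle k spans `[0.25k, 0.25(k+1))` years from
model start and is discounted by `(1+r)^(−0.25k)` (annual rate r = 0.05 for
both costs and effects, settable separately; range 0–0.08). Residence-based
rewards — quarterly shares of the annual state costs ($1,420 non-disabling,
$2,182 disabling) and utilities (0.76 / 0.21, recurrent 0.42, dead 0) — are
valued by default on *half-cycle-corrected* membership (the mean of the
cycle's start and end occupancy, i.e. the trapezoid rule), the standard
correction for a discrete-time approximation of continuous residence. The
recurrent-event cost ($1,599) is charged once per entry into a tunnel state
(cycle-start tunnel occupancy), since it prices an event, not residence;
tunnel occupants carry the recurrent utility for that cycle and no
maintenance cost. We adopted the half-cycle correction after a systematic
comparison of the open structural conventions against the published
base-case table: with it, all eight published totals/ICERs are matched to
≤1% (ICER $10,012 vs $10,050 per QALY); without it the model overstates
accruals by 1–2% uniformly. `half_cycle_correction=False` restores
cycle-start valuation.

## Outcomes

Arm totals are decision-tree plus Markov discounted sums. The ICER is
computed from unrounded totals (the published table's rounded incrementals
are mutually inconsistent, e.g. 13,310/1.32 = 10,083 against a printed
10,050); life-year ICERs use discounted life-years. Dominance is flagged
instead of forming a ratio when the incremental cost and effect disagree in
sign appropriately. Classification against willingness-to-pay uses the
1x / 3x per-capita-GDP thresholds ($12,551 / $37,654 per QALY): below,
between, above → highly cost-effective / cost-effective / not
cost-effective. Net monetary benefit (`wtp x QALY − cost`) backs the
acceptability computations so that non-positive incremental effects need no
division.

## Sensitivity analyses

**One-way (tornado).** Every input with a printed range is set to its low
and high bound with all else at point values. Varying one component of an
outcome triple rescales the other two proportionally to restore sum 1. The
pooled relative risks act through the SR-arm distribution (RR x control
triple, renormalised, other RRs at point); with this mechanism the RR of
non-disabling outcome and the SR-arm non-disabling proportion are the two
dominant drivers, though their order swaps relative to the published figure
because the RR's printed range is the wider of the two — the two bars vary
nearly the same quantity, as the pooled RRs essentially equal the trial's
own outcome ratios. The single discount-rate entry moves the cost and
effect rates together. No tornado entry exceeds the $37,654 threshold.

**Scenarios.** (1) device cost x0.5; (2) x1.5; (3) effects undiscounted
with costs still at 5% (the published scenario changes effectiveness but
not costs); (4) SR-arm efficacy replaced by pooled relative risks applied
to the control distribution. Scenario 4's published control-arm row used an
unprinted pooled control distribution, so only its SR-arm construction is
reproducible; our scenario 4 deliberately leaves the BMM arm at trial
values and its ICER is therefore expected to differ from the published one.

**Subgroups.** Start age shifts the background-mortality band lookup; sex-
specific runs are supported by supplying a custom mortality table (none is
shipped, as the sex-specific life table is not in the main text).

**Horizon.** The pipeline is truncated at each horizon (the first cycle is
always the decision tree) and the deterministic ICER recorded, along with
the smallest horizons reaching each threshold. With default inputs the
3x-GDP crossing is at 3 years. The 1x-GDP crossing is knife-edge: the
10-year ICER is within 2% of the $12,551 threshold under every structural
convention we examined (our default gives $12,786, crossing at 11 years). A
PSA-per-horizon acceptability variant can be assembled from `run_psa` with
a truncated horizon.

## Probabilistic sensitivity analysis

Second-order distributions follow pharmacoeconomic convention: beta for
probabilities and utilities, gamma for costs and relative risks, Dirichlet
for outcome triples, fixed for inputs without ranges (all long-term
transition rows). Fitting matches the mean to the point estimate and the
printed range to the central 95% interval (`range_mode="ci95"`; a `minmax`
mode treats ranges as uniform-width supports with clipping — whether the
printed ranges are 95% CIs or min–max bounds is not stated). The Dirichlet
concentration minimises the squared error between its marginal variances
and the range-implied variances; a single concentration is a compromise
across the three components. Sampled sets must satisfy every parameter-set
invariant; violating draws (in practice a recurrent utility sampled outside
the non-disabling/disabling ordering, ~8% of draws) are rejected and
redrawn, and the rejection count is reported.

By default the PSA samples costs, utilities, acute event proportions and
the non-stroke-mortality RR, holding the trial 90-day efficacy
distributions and the discount rates at their points — these are examined
in the scenario/one-way analyses, and the published acceptability
statistics (0.9854 at 1x GDP, CEAC median crossing ≈ $10,030) correspond to
this dispersion; sampling the efficacy triples as well roughly doubles the
ICER spread. `sample_efficacy_distributions=True` / `sample_discount_rates=True`
enable the fully probabilistic variant. All blocks are sampled
independently (no correlation structure). Runs are bit-reproducible given
the seed.

## Synthetic parameter generator

`synthetic.generate_parameter_set` emulates the *structure* of the inputs —
Dirichlet outcome triples, diagonally dominant quarterly transition rows
with the recurrent-after-disabling restriction, strictly age-increasing
background mortality, log-uniform USD-scale costs, ordered utilities —
over a realistic dynamic range without reproducing any published table.
Passing property tests on generated sets therefore demonstrates structural
correctness (mass conservation, monotonicity, equivariance), not clinical
realism: generated sets have no correlation between efficacy and cost
blocks, and their transition rows are not calibrated to any cohort.
`degenerate_fixtures` provides closed-form edge cases (identical arms, unit
utilities, no discounting, negligible background mortality, an immortal
undiscounted chain) used to pin exact engine identities.

## Numerical choices and limitations

* Probability rows and outcome triples must sum to 1 within 1e−9; printed
  triples off by up to 1% are renormalised (printed rounding).
* Matrices are cached per (era, age-band); occupancy propagation is exact
  linear algebra, no sampling in the deterministic pipeline.
* Ages beyond 85 use the terminal mortality band for all remaining cycles.
* Default problem sizes: 80 quarterly cycles (20 years), 10,000 PSA
  iterations in the reproduction script and 2,000 in the test suite's
  scaled-down PSA check.
* The model is cohort-level throughout: no microsimulation, no
  patient-level heterogeneity beyond start age, no time-varying costs
  beyond discounting, and no value-of-information analysis.
* Currency is consumed as printed (2021 USD); no inflation engine.
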