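# strokecea

A decision-tree + Markov cohort model for the cost-effectiveness of
stent-retriever mechanical thrombectomy (SR) added to best medical
management (BMM), versus BMM alone, in basilar artery occlusion (BAO)
stroke — from the Chinese healthcare-system perspective, in 2021 USD.

It is written for health economists and stroke researchers who want a
transparent, scriptable, fully tested implementation of this class of
hybrid model: a 90-day decision tree over modified-Rankin-Scale outcomes
(mRS 0–2 non-disabling / 3–5 disabling / 6 dead) feeding a 20-year,
quarterly-cycle Markov cohort with recurrent-stroke tunnel states,
age-dependent background mortality, and 5% annual discounting.

## The model in brief

For each strategy *a*, total discounted cost and effect are

```
C_a = C_tree(a) + Σ_k  c(s_k) (1+r)^(-t_k)          t_k = 0.25 k
E_a = E_tree(a) + Σ_k  u(s_k) Δt (1+r)^(-t_k)
```

where `s_k` is the cohort state-occupancy vector propagated through
row-stochastic quarterly transition matrices (era-dependent, with
background mortality composed as a competing risk), and the headline
statistic is the incremental cost-effectiveness ratio

```
ICER = (C_SR − C_BMM) / (E_SR − E_BMM)   [USD per QALY]
```

judged against willingness-to-pay thresholds of 1x and 3x per-capita GDP
($12,551 / $37,654 per QALY). Scenario, one-way (tornado), subgroup,
time-horizon and probabilistic (Monte Carlo) sensitivity analyses are all
first-class operations. See `docs/methods.md` for assumptions and
conventions.

## Worked example

```python
from strokecea import default_parameters, run_base_case

ps = default_parameters()          # shipped trial + cost/utility inputs
res = run_base_case(ps)
print(f"BMM   : ${res.reference.total_cost:,.0f}  "
      f"{res.reference.total_qaly:.2f} QALY  {res.reference.total_ly:.2f} LY")
print(f"SR+BMM: ${res.comparator.total_cost:,.0f}  "
      f"{res.comparator.total_qaly:.2f} QALY  {res.comparator.total_ly:.2f} LY")
print(f"ICER  : ${res.icer_qaly:,.0f}/QALY  (${res.icer_ly:,.0f}/LY)  "
      f"-> {res.classification}")
```

prints

```
BMM   : $8,756  1.45 QALY  3.29 LY
SR+BMM: $22,126  2.79 QALY  4.73 LY
ICER  : $10,012/QALY  ($9,317/LY)  -> highly_cost_effective
```

i.e. adding thrombectomy costs about $13,370 more per patient over 20
years, buys about 1.34 quality-adjusted life years, and at ~$10,000 per
QALY sits below the one-GDP-per-capita threshold — highly cost-effective.

The same pipeline is available from the shell:

```
strokecea base-case                      # Table-style report + manifest
strokecea scenarios                      # four alternative scenarios
strokecea tornado                        # one-way sensitivity, CSV
strokecea psa --iterations 10000 --seed 1  # CE plane + CEAC
strokecea horizon                        # ICER vs time horizon
strokecea subgroup --start-age 70
```

Each command writes plot-ready CSV/JSON plus a run manifest (input digest,
engine options, seed, version) into `results/`.

Inputs live in a single validated JSON/YAML file
(`src/strokecea/data/baoche_2021_usd.json` is the shipped default); edit a
copy and pass `--params` to run the model on your own numbers. The
`strokecea.synthetic` module generates random valid parameter sets for
property testing.

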