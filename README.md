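# rvdys

Right-ventricular (RV) mechanical dyssynchrony and post-systolic
contraction (PSC) from multi-view cardiac-MR strain curves, with a
proportional-hazards survival analysis and a synthetic-cohort generator.

## The problem

In pulmonary arterial hypertension (PAH) the right ventricle fails not
only globally (lower ejection fraction, lower global strain) but also
*inefficiently*: its walls shorten at different times within the cardiac
cycle (dyssynchrony), and some walls keep contracting after the pulmonary
valve has closed (post-systolic contraction). Quantifying these timing
abnormalities from feature-tracked strain curves in multiple imaging
views — RV three-chamber (RV3ch), four-chamber (4ch), and midventricular
short-axis (SAX) — and relating them to transplantation-free survival is
the purpose of this package. It is aimed at researchers in cardiac
imaging and biostatistics who have per-wall strain curves (or tracked
endocardial contours) and outcome data, or who want a fully synthetic but
statistically faithful cohort to develop against.

## The statistics at the core

For each of six RV wall regions w (anterior/inferior in RV3ch,
lateral/septal in 4ch, free wall/septal in SAX) the time-to-peak strain
ttp_w is the time from the R wave to the maximum-magnitude strain of that
wall's curve. The **dyssynchrony index** over a wall set W is

    index(W) = 100 · SD({ttp_w : w ∈ W}) / RR        [% of RR interval]

with SD the sample (n−1) standard deviation and RR the cycle length; W is
all six walls (three views), the four 4ch+SAX walls (two views), or a
single view's two walls. **PSC** is present in a view when the free-wall
peak occurs more than one timeframe (RR / n_phases) after pulmonary valve
closure; its signed duration is t_peak − t_PVC, in ms and in % of RR.
Survival is modelled with the Cox proportional-hazards partial
likelihood, maximized by Newton-Raphson with Breslow (default) or Efron
tie handling: univariate fits per variable, then age-adjusted bivariate
fits for variables passing a p < 0.1 screen.

## Worked example

```python
from rvdys import SimulationConfig, generate_cohort, metrics_table
from rvdys.stats import univariate_screen

sim = generate_cohort(SimulationConfig(n=200, seed=1))
mt = metrics_table(sim.cohort, sim.strain)
df = sim.cohort.to_dataframe().merge(mt, on="patient_id")

print(f"three-view index: {df['dys3_pct'].mean():.1f} "
      f"+/- {df['dys3_pct'].std():.1f} % of RR")
print(f"4ch global longitudinal strain: {df['gls_4ch'].mean():.1f} %")
print(f"PSC prevalence in SAX: {100 * df['psc_sax'].mean():.0f} %")
out = univariate_screen(df, ["dys3_pct"], threshold=1.0)
row = out["dys3_pct"]["bivariate"].summary().loc["dys3_pct"]
print(f"age-adjusted HR per 1% dyssynchrony: {row['hr']:.2f} "
      f"({row['ci_lo']:.2f}-{row['ci_hi']:.2f}), p={row['p']:.3f}")
```

prints

```
three-view index: 8.8 +/- 3.5 % of RR
4ch global longitudinal strain: 14.9 %
PSC prevalence in SAX: 45 %
age-adjusted HR per 1% dyssynchrony: 1.05 (0.99-1.12), p=0.124
```

The cohort mean index sits near its configured 9% of RR, global strain
near 14.8%, and roughly half the cohort shows PSC in SAX. The
age-adjusted hazard ratio estimates the generating effect (1.10 per 1%
of dyssynchrony) noisily at n = 200 — at this cohort size the confidence
interval still brackets 1, which is exactly why parameter recovery is
checked at larger n in the test suite.

The same pipeline runs from the shell:

```sh
rvdys simulate --config config.yaml --out run/
rvdys metrics  --cohort run/cohort.csv --strain run/strain.csv --out run/metrics.csv
rvdys survival --cohort run/cohort.csv --metrics run/metrics.csv --out run/results.json
rvdys report   --results run/results.json --out run/table.txt
```

where `config.yaml` needs at least `n:` and `seed:` (all other generator
knobs have cohort-calibrated defaults; see `docs/methods.md`).

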