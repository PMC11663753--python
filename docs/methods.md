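# Methods

This note documents the models and procedures implemented in `rvdys`,
the choices made where the design was genuinely open, and what the
synthetic cohort does and does not emulate.

## Strain from tracked contours

Feature tracking itself is out of scope: the package consumes its output,
either strain curves directly or point-corresponded endocardial contours
per time phase. Strain is length-based Lagrangian strain,

    s(t) = 100 · (L(t) − L(0)) / L(0),

with L the polyline length of the tracked contour and frame 0 the
end-diastolic reference (s(0) ≡ 0). Shortening is negative; tabulated
global strains are magnitudes, which reconciles negative curves with the
positive values conventionally reported. Longitudinal strain is computed
in the RV3ch and 4ch views, circumferential in SAX. This length-based
formulation is a documented stand-in for the proprietary tracking
software's internal strain definition, which is not public; every
downstream statistic depends only on peak timing and magnitude, which the
stand-in preserves. Two exact properties pin the implementation down:
rigid motion of any frame leaves the curve unchanged, and uniform
coordinate scaling by c at frame k gives exactly 100(c−1) at k.

## Peak detection

The peak is the maximum-|s| frame over frames 1..T−1 (frame 0 is
identically zero by construction), ties broken toward the earliest frame.
The search stays on the native frame grid with no sub-frame
interpolation: the PSC rule is stated in units of one timeframe, which is
only meaningful on that grid. The frame duration is RR / n_phases —
cine reconstructions are uniform in time (typically 25–30 phases per
cycle). Segmental curves belonging to one wall are averaged point-wise
into the wall curve before peak detection.

## Dyssynchrony index

SD of time-to-peak across a wall set, as a percentage of RR. The SD uses
the sample (n−1) denominator — the convention of the mainstream
statistics packages used for this kind of analysis — switchable to n via
`ddof`. Wall sets: all six walls (three views), the four 4ch+SAX walls
(two views, the reported fallback when RV3ch is missing), or one view's
two walls. Because pulmonary valve closure is a single per-patient
constant, the SD of (ttp − t_PVC) equals the SD of ttp, so referencing
peaks to the valve closure or to the R wave yields the same index; the
test suite asserts this equivalence.

## Post-systolic contraction

PSC in a view is present when peak strain falls strictly more than one
timeframe after pulmonary valve closure; exactly one timeframe is not
PSC. Duration is t_peak − t_PVC, signed, reported for every patient (not
clamped at zero, not conditioned on presence), in ms and in % of RR. Two
open points are resolved as package defaults and are configurable:

- **Which curve represents a view**: the free wall (RV3ch: point-wise
  mean of anterior and inferior; 4ch: lateral; SAX: free wall), being the
  RV-specific choice and least contaminated by septal interaction.
- **Closure-time provenance**: the closure time is one physiologic event
  per patient; a view-specific measurement (RV3ch- or SAX-derived) takes
  precedence when recorded, otherwise the RVOT-derived value is used for
  all views.

## Cox proportional-hazards fitting

The partial likelihood is maximized by Newton-Raphson with step-halving;
covariates are centered internally (the partial likelihood is invariant
to covariate shifts, so this changes nothing but floating-point range).
Tie handling is Breslow by default with Efron available by flag.
Convergence requires max |score component| < 1e−9 within 50 iterations;
the step-halving acceptance tolerance is relative to |log PL| so that
float-level noise near the optimum cannot stall the iteration. Standard
errors come from the observed information; CIs and p-values are
two-sided Wald. Monotone likelihood (perfect separation) is flagged as
non-convergence — detected by a non-finite or exploding standard error —
rather than raised, since screening loops must survive degenerate
variables. The fitter is validated against a brute-force grid
maximization of the same likelihood and against an independent
implementation (lifelines, Efron ties) in the test suite.

The analysis chain mirrors a pre-specified protocol: univariate fits for
each candidate variable, and an age-adjusted two-covariate fit for every
variable with univariate p < 0.1 (never more than two covariates; age is
the sole adjustment variable). No multiple-testing correction is applied
anywhere, by protocol. Group comparisons are gated by Shapiro-Wilk at
0.05 into t-test with mean ± SD versus Mann-Whitney U with median [IQR]
(IQR reported as a single width, quartiles by linear interpolation);
2×2 tables use Pearson chi-square without continuity correction, which
is required to reproduce published contingency-table p-values.

## Synthetic cohort

The generator emulates the *statistical structure* the pipeline assumes,
not cardiac mechanics. Per wall,

    s_w(t) = −A_w · φ((t − τ_w) / (width · RR)) + ε(t),

with φ a raised-cosine bump (φ(u) = (1 + cos 2πu)/2 on |u| ≤ 1/2): only
peak timing and magnitude matter to every downstream statistic, so a
physiologic pressure-volume model would add nothing testable. Peak times
are τ_w = τ̄·RR + RR·(D/100)·z_w where D is the patient's latent
dyssynchrony level and z the standardized (mean 0, sample SD 1) offsets
over the six walls — the realized six-wall time-to-peak SD equals
RR·D/100 exactly before grid sampling, which makes D recoverable and
parameter recovery a sharp test (measured-vs-latent regression slope 1
within 5% at zero noise; grid quantization adds ~1% of RR in quadrature).

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| heart rate | 78 ± 13 bpm | cohort biometrics being emulated |
| age | 58 ± 19 y, ≥ 16 | cohort biometrics; adult inclusion bound |
| n_phases | 25 | typical cine reconstruction |
| D (dyssynchrony) | 9 ± 3 % of RR, ≥ 0 | cohort three-view index |
| A (peak magnitude) | 14.2 / 14.8 / 8.7 % by view, SD 3 | cohort global strains |
| τ̄ | 0.46 · RR | see PSC paragraph below |
| PVC time | 0.42 · RR | end-ejection at a typical systolic fraction |
| width | 0.8 · RR | smooth unimodal systolic curve |
| noise | 0.3 % strain | modest measurement noise |
| β_D | ln(1.10) per % | dyssynchrony-survival effect size |
| β_age | ln(1.04) per year | age-survival effect size |
| h0, horizon, accrual | 5e−4 /mo, 180 mo, 176 mo | calibrated so defaults yield ~60% events and median follow-up ≈ 37 months |
| RV3ch missing | 38.6 % | fraction of patients lacking the newest view |

Event times are exponential with rate h0·exp(β_D·D + β_age·age);
censoring is administrative (uniform entry over the accrual window
against a fixed horizon), so follow-up is min(T, C).

**PSC prevalence is emergent by default.** With τ̄ at 0.46·RR and valve
closure at 0.42·RR, the per-view free-wall peak lands beyond the
one-frame threshold for roughly half of patients, reproducing the
~40–55% per-view prevalence without a separate mechanism. An explicit
forcing knob (`psc_prob_*` + exponential shift beyond PVC + 1.5 frames)
exists for constructing guaranteed positives in tests; it is off (None)
by default because unconditionally shifting walls on top of the latent D
would inflate the realized time-to-peak SD and break the index
calibration.

What the generator does **not** emulate: realistic curve morphology
beyond a single systolic bump (no diastolic dynamics, no biphasic or
notched patterns), spatially correlated tracking error, inter-vendor or
inter-scanner strain differences, association between dyssynchrony and
hemodynamics (mPAP/PVR are drawn independently of D), and informative
censoring. Tests passing on synthetic cohorts therefore validate the
*computational* chain — curve → peaks → indices → survival model — not
the clinical robustness of feature tracking on real images.

## Numerical choices and degenerate inputs

- All-zero strain series (untracked wall) raise a dedicated no-peak
  error; the per-patient orchestration converts it to a missing value
  with a flag, and any wall set containing that wall is skipped.
- Peak ties go to the earliest frame, making results independent of
  storage order.
- Truncated normal draws use rejection sampling from a single
  `numpy.random.Generator`, so every output is reproducible from one
  seed; CSV outputs are byte-identical across runs with the same config.
- CSV interchange uses 6 significant digits; indices are full precision
  internally and rounded only at presentation.
- The 30-day RHC-to-CMR window for the hemodynamic subgroup is inclusive
  (≤ 30) and uses the absolute difference, since the direction of the
  gap is not meaningful for eligibility.

## Problem sizes used in the checks

The acceptance script fits at n = 2000 (recovery SE ≈ 0.01 on the log
hazard ratio, well inside the ±0.03 band checked); calibration checks
use n = 1000 cohorts; Wald coverage uses 600 replicates at n = 300;
large-n consistency checks go to n = 5000. These sizes make the
stochastic checks sharp while keeping the full suite under a minute of
compute on one core.

## Known limitations

- The dyssynchrony index is grid-quantized: at 25 phases, one frame is
  4% of RR, so per-patient indices carry ~1% of RR quantization noise.
- The Cox fitter handles right censoring and ties only — no delayed
  entry, time-varying covariates, or stratification.
- The survival generator's exponential baseline cannot represent
  non-monotone hazards; it suffices for effect-size recovery, which is
  all the analyses need.
- PSC representative-wall choice is a convention; with a different
  representative (e.g. septal curves) per-view PSC prevalences would
  change.
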