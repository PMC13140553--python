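# Methods

`picpipe` estimates the contribution of persistent inward currents (PICs)
to human motoneuron firing from motor-unit (MU) spike trains recorded
during triangular isometric ramp contractions, and tests before/after
condition contrasts with linear mixed-effects models. This note documents
the models, the estimators, the synthetic motoneuron pool used for
validation, and the numerical choices behind them.

## The measurement model

Input to the pipeline is the output of high-density surface EMG
decomposition: per motor unit, a train of firing times within a 20 s
triangular dorsiflexion ramp (10 s up to 20% of the participant's maximal
voluntary torque at 2%/s, 10 s back down), together with the torque trace
and the decomposition quality (pulse-to-noise ratio, PNR). Decomposition
itself is upstream and out of scope; the pipeline enforces the quality
gate (PNR ≥ 30 dB) on its inputs. Units are assumed tracked across the
"before" and "after" ramps of a condition — the same `unit_id` in both
phases denotes the same motoneuron — which is what licenses the
within-unit repeated-measures analysis.

### Torque conditioning and trial QC

Torque is low-pass filtered with a 5th-order Butterworth at 10 Hz and
expressed as % of peak torque. The filter is applied forward–backward
(zero phase), so the effective magnitude response is the single-pass
response squared; we accept this because any phase lag would bias
recruitment/derecruitment threshold timing, which matters more here than
an exact printed magnitude response. Edges use reflective padding.

A trial fails quality control when the instantaneous gap between
performed and requested torque exceeds 5% of peak anywhere in the ramp
("abrupt/steep" deviation); the whole contraction is then discarded. The
detector is deliberately simple — a pointwise threshold on the filtered
trace — because the exclusion rule is stated as a magnitude, not a
detector. The unsigned area between performed and requested paths
(trapezoidal, in %·s) is reported as a secondary tracking-consistency
metric. Whether the 5% rule should be evaluated on raw or filtered
torque is ambiguous; we use filtered, which is slightly more permissive
against single-sample spikes.

### Discharge-rate smoothing

Firing times become instantaneous discharge rates as reciprocal
inter-spike intervals, assigned at the interval's closing spike
(`rate_k = 1/(t_k − t_{k−1})`). The rate profile is then smoothed with
ε-insensitive support vector regression (RBF kernel) and evaluated on a
uniform 0.01 s grid spanning recruitment (first firing) to derecruitment
(last firing).

Hyperparameters (package conventions, exposed in `SVRConfig`):

| parameter | default | rationale |
|---|---|---|
| kernel length scale | 0.4 s | tracks physiological rate modulation (~seconds), rejects ISI jitter |
| C | 50 | stiff enough to follow the ramp's rise and fall |
| ε | 0.01 pps | the tube is kept narrow: tube slack translates one-for-one into landmark-reading error in ΔF; smoothing comes from the kernel, not the tube |

A wider tube (ε ≈ 0.1) lets the fitted curve sit anywhere inside a
±0.1 pps band, which alone exceeds the ΔF accuracy we validate against
on noiseless data; ε = 0.01 removes that slack at negligible cost in
smoothness. Ties at the curve maximum resolve to the earliest grid
point. Units with fewer than 4 firings are dropped (counted, logged).
Known artefact: the smoother rounds the corner at the rate apex over
roughly one length scale, which can pull the late ascending curve
slightly below its chord; on perfectly linear (zero-acceleration)
profiles this produces small *negative* brace heights (≈ −4 % rTri)
rather than exactly zero.

### Paired-MU ΔF

For every ordered pair in a trial with the control (lower-threshold)
unit recruited before the test (higher-threshold) unit, the pair enters
the analysis iff all four criteria hold:

1. rate–rate Pearson correlation ≥ 0.7, computed between the two
   smoothed curves resampled on their common support at the grid step;
2. recruitment separation > 1 s;
3. control rate modulation — control peak rate minus control rate at
   test recruitment — > 0.5 pps;
4. control derecruited after the test unit.

Criterion 3 is stated in the source literature as a difference that
would be negative for any sensible unit ("rate at test recruitment minus
peak > 0.5"); it is implemented here in its standard orientation
(peak − rate-at-test-recruitment > 0.5 pps).

ΔF = control smoothed rate at test recruitment − control smoothed rate
at test derecruitment, read at the nearest grid point (grid step 0.01 s
makes interpolation error negligible). Per-test-unit ΔF is the
unweighted mean over that unit's valid controls. A test unit with no
valid pair keeps its other metrics but has no ΔF.

### Brace height and attenuation slope

The ascending phase (recruitment to smoothed-rate peak) is mapped to the
unit square: time and rate each affinely rescaled to [0, 1]. The chord
(hypotenuse) joins (0,0) to (1,1). Brace height is the
largest-magnitude signed orthogonal deviation of the curve from the
chord, normalised by the distance from the right-angle vertex (0,1) to
the chord: `brace = 100·max(y−x)` % rTri. The unit-square normalisation
makes the quantity invariant to separate affine rescalings of either
axis (property-tested), which is what makes "% of the right triangle"
well defined; a curve bulging below the chord reports a negative value.
Time (not torque) is the abscissa. Degenerate ascending phases (peak at
recruitment, or zero rate range) drop the unit from geometry metrics.

Attenuation slope is the OLS slope of smoothed rate (pps) against
filtered torque (%MVT) over the grid samples from the brace-height
insertion point (the argmax of the deviation) to the ascending peak,
with torque linearly interpolated onto the rate grid. The %MVT abscissa
is forced by the quantity's units (pps/%MVT). Saturated, PIC-dominated
units flatten against torque; units still tracking drive linearly do
not.

Recruitment/derecruitment thresholds are the filtered torque (% of
peak) at the unit's first/last firing; peak discharge rate is the
smoothed-curve maximum.

## The synthetic motoneuron pool

The generator is phenomenological, not conductance-based: the pipeline
needs firing-rate phenomenology with controllable ground truth, not
biophysics. Common drive `E(t)` (%MVT) follows the triangular target
plus slow (~1 Hz) tracking noise. Unit *i* (threshold θᵢ, gain gᵢ,
hysteresis δᵢ) is recruited when E crosses θᵢ on the ascent and fires
until E falls below θᵢ − δᵢ on the descent. While active its rate is

    rᵢ(t) = r_min + gᵢ·(E − θᵢ) + A·(1 − exp(−max(E − θᵢ, 0)/s))

— a linear drive term plus a saturating acceleration of amplitude A
(pps) and scale s (%MVT) emulating PIC amplification. With A = 0 the
model is linear and the pair-level ΔF ground truth is exactly
g_control · δ_test.

Spikes are an inhomogeneous renewal process: gamma ISIs with unit mean
and configurable coefficient of variation in operational time (the
integrated rate), mapped back through time rescaling. At CV = 0 the
generator instead solves the fixed point `t_k − t_{k−1} = 1/r(t_k)`, so
the reciprocal-ISI samples the pipeline computes lie exactly on the true
rate curve; the CV→0 limit of time rescaling would leave a half-ISI lag
(~0.15 pps ΔF bias) that has nothing to do with the estimators under
test.

**Realized hysteresis.** A spike train necessarily ends at its last
spike, up to one ISI before the exact derecruitment crossing, so the
hysteresis a train *exhibits* is slightly below the nominal δ. The
ground truth records both: `delta` (nominal) and `delta_realized`
(θ minus the drive at the last emitted spike); recovery oracles score
against the realized value. Equivalently: the generator's truth is what
it actually did, not what it was asked to do.

Defaults emulate the tibialis anterior protocol: 21 participants, 15
units per trial, thresholds uniform on 1–18 %MVT, gain 0.5 pps/%MVT
(±20% per-unit jitter), r_min 6 pps, acceleration A = 3 pps with
s = 5 %MVT, hysteresis uniform on 1–4 %MVT, ISI CV 0.15, torque at
256 Hz with 0.15% measurement noise and 0.4% tracking noise, peak
torque 54 N·m. Per-unit hysteresis is capped at 0.9·θ so every unit
derecruits within the ramp; explicitly supplied parameters with δ ≥ θ
are a fatal error. Condition effects apply to "after" trials only: a
hysteresis shift (raising ΔF by gain·shift in the linear regime) and/or
an additive rate shift (moving peak rates); by default the two
high-impulse handgrip conditions carry shifts producing ΔF effects of
+0.33 and +0.24 pps.

What the generator does **not** emulate: decomposition errors (spurious
or missed spikes, unit merging), common-drive fluctuations beyond the
tracking-noise band, rate adaptation/fatigue within the ramp, and any
dependence of the rate on drive history other than the on/off
hysteresis. Passing recovery tests therefore demonstrates estimator
correctness under clean phenomenology, not robustness to decomposition
artefacts.

## Mixed-effects contrasts

Per response (ΔF, brace height, attenuation slope, peak discharge rate,
recruitment/derecruitment threshold), the model has fixed effects for
phase (before/after), condition, and their interaction, plus optional
unit-level covariates centred at their grand mean; random structure is a
participant intercept plus a variance component for the unit nested in
the participant (optionally a random slope on phase). Default
covariates: ΔF adjusts for peak discharge rate and recruitment
threshold; brace height, attenuation slope and peak discharge rate
adjust for recruitment threshold; the threshold responses take none.
Fits are REML (statsmodels `MixedLM`); a singular unit-level component
triggers a refit without it (warned).

The contrast of interest is the after − before estimated marginal mean
difference per condition — with centred covariates and no
phase×covariate interaction this is the phase coefficient plus the
phase×condition interaction — with Wald 90/95% CIs (normal
approximation). The standardised effect is d = difference/σ with σ² the
sum of all variance components plus residual variance (configurable in
principle; residual-only is a defensible alternative, and σ enters only
the effect-size label, not the CIs). Covariate-model selection
(`compare_covariate_models`) refits the four candidate ΔF models under
ML, reporting AIC/BIC; within `fit_contrasts` the reported AIC/BIC are
from the fit actually used and comparable only across equal fixed
effects. The published analysis used a robust (iteratively reweighted)
mixed-model estimator; this package fits the standard Gaussian REML
model, so point estimates are expected to agree with published values
to within their confidence intervals rather than exactly.

In a balanced design with no covariates the model's contrast equals the
raw mean of participant-level (after − before) means to 1e-6
(regression-tested), which is the sanity anchor for everything else.

Only units observed in both phases enter contrasts
(`matched_outcomes`); units present in one phase keep their per-unit
metrics but cannot contribute a within-unit difference.
`complete_case_subset` restricts to participants with all 4 conditions ×
2 phases for sensitivity analyses. An import adapter
(`read_unit_table` + a column map) lets the stats stage re-analyse an
externally produced per-unit table, e.g. a published dataset.

## Validation scenarios and their sizes

`picpipe.validation` holds the ground-truth scenarios run by the test
suite and by `scripts/acceptance.py`. Sizes are the package's choices,
balancing Monte-Carlo error against minutes-on-one-CPU:

* **Noiseless ΔF** — linear model, no noise: every valid pair's ΔF must
  match gain×hysteresis within 0.05 pps (measured max ≈ 0.03, the
  smoother's residual).
* **Hysteresis grid** — δ ∈ {1,2,3,4} %MVT at ISI CV 0.15, 30-unit
  pools × 20 replicates: the median pair error stays within ±0.5 pps
  (measured ≈ −0.2 pps, the smoothing lag under jitter).
* **Contrast recovery** — +0.30 pps injected into the two high-impulse
  conditions of an 8-participant × 12-unit study; 30 replicate studies,
  each fit with the ΔF mixed model. The *mean* recovered contrast must
  sit within ±0.05 pps of the injection (Monte-Carlo SE ≈ 0.02 at this
  size; a single replicate's contrast has SE ≈ 0.10–0.15, so a
  single-run check at ±0.05 would be noise, not a bias test). The
  scenario uses the linear rate model — with the saturating acceleration
  a hysteresis shift injects more than gain×shift for closely spaced
  pairs, so "+0.30 pps" is only well defined at A = 0 — and thresholds
  on 5–18 %MVT so the shifted hysteresis is feasible for every unit
  (with lower thresholds the generator's δ < θ cap would silently
  reduce the injected effect to ≈ 0.26 pps). Null-condition 95% CIs
  must cover zero in ≥ 90% of replicates.
* **Null coverage** — 50 replicate null studies (6 × 6): ~95% of
  per-condition 95% CIs cover zero.
* **Brace height vs acceleration** — noiseless pools over A ∈ 0…4 pps
  at fixed saturation: mean brace height increases monotonically.

## Known limitations

* ΔF landmark readings inherit the smoother's local bias (corner
  rounding near the apex, edge behaviour within ~one length scale of
  recruitment/derecruitment); pairs whose test unit derecruits very
  close to its control's own derecruitment read the control curve in
  its edge region.
* The rate model has no history dependence beyond on/off hysteresis, so
  simulator-true ΔF is a pure function of drive levels; real ΔF mixes
  test-unit hysteresis with control-unit rate adaptation.
* The robust-estimator difference from the published analysis is not
  quantified here; only a standard REML fit is provided.
* Recruitment/derecruitment thresholds depend on the torque trace's
  noise at two time points and are the least stable outputs, as in real
  data.
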