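# Methods

## Signal model and T2 estimation

Each pixel of a multi-spin-echo acquisition is modelled as a pure
mono-exponential decay

    S(TE) = S0 · exp(−TE / T2),

sampled at TE = n·8.38 ms, n = 1…12. Only echoes 2–7 enter the fit: the
first echo is excluded because stimulated echoes bias it, the late echoes
(TE > 60 ms) because their SNR is too low. Echo indices are 1-based
everywhere in the API.

The default estimator is unweighted ordinary least squares on
ln S versus TE ("loglinear"), vectorised over all masked pixels with one
shared pseudo-inverse; it is deterministic and exact on noise-free data. An
optional "nonlinear" refinement runs Levenberg–Marquardt on the signal
itself, initialised from the loglinear estimate; on Rician magnitude data at
SNR ≈ 50 both estimators keep the median T2 bias well below 1 % (the
acceptance script reports it), but the nonlinear path is the right default
when SNR is lower. No noise-floor offset term is included, so T2 is
systematically overestimated once the Rician floor dominates (roughly
SNR ≲ 10 at the last fitted echo); this is a known limitation, not
corrected.

Numerical choices: a pixel with any non-positive signal in the fit subset is
marked unfittable (NaN, never 0 ms); T2 estimates are clamped to
[1, 300] ms and flagged when the raw estimate fell outside; R² is computed
in the signal domain and a perfect fit on constant data counts as R² = 1.
Downstream ROI statistics use pixels with R² ≥ 0.7 by default (configurable)
— with the default phantom noise this excludes essentially nothing, but it
protects real low-SNR data.

## ROI layers

The whole-sample mask (an input, drawn conservatively in practice) is split
into equally thick superficial and deep layers per image column: a column of
height h contributes its top ⌈h/2⌉ pixels (surface side, row 0) to the
superficial layer and the rest to the deep layer. Odd heights therefore
favour the superficial layer by one pixel — "equally thick" leaves the tie
unspecified, so the choice is documented and tested. Columns are image
columns, not surface-normal chords; for the near-flat samples this pipeline
targets the difference is negligible. A column whose mask is not vertically
contiguous is an error rather than silently split.

## Texture features

The T2 map inside an ROI is uniformly quantized into L = 32 levels over a
fixed 0–120 ms range by default. Fixed binning keeps maps comparable across
time points — per-map min-max stretching (available as `roi_minmax`) would
partially normalize away the longitudinal signal. Symmetric GLCMs are
accumulated for a single-pixel offset along 0°, 45°, 90° and 135°; a pair
contributes only if both pixels are inside the ROI and carry a defined T2,
so boundary pairs are discarded instead of padded (padding would fabricate
texture at the sample edge). From each normalized matrix p(i,j):

    contrast    = Σ p(i,j)(i−j)²
    homogeneity = Σ p(i,j)/(1+|i−j|)
    energy      = Σ p(i,j)²                 (angular second moment)
    variance    = Σ p(i,j)(i−μ)²,  μ = Σ i·p(i,j)

Feature values (not matrices) are arithmetic-averaged over the orientations
that produced at least one pair; "energy" means ASM, not its square root.
Variance is reported in quantized-level units, with an optional ms²
rescaling through the bin centers — absolute texture magnitudes therefore
depend on (L, range) and are comparable only within one configuration; the
scientifically meaningful content is the direction and ordering of changes.

## The phantom cohort

The generator emulates ~15 mm wide cartilage cross-sections at
0.23 mm/pixel (≈ 65 × 11 tissue pixels plus background padding), one
mid-sagittal slice per sample, with a mildly undulating articular surface
(±1 px) so the per-column layer split is exercised on non-rectangular
masks. True T2 interpolates linearly with depth between a superficial and a
deep baseline; per-sample baselines are drawn from group-wise normal
distributions (superficial ≈ 37–43 ± 4–6 ms, deep ≈ 26–29 ± 3–6 ms,
superficial > deep enforced by rejection), reproducing the depth-wise
stratification of intact cartilage.

Three arms evolve over t0 (baseline), t1 (immediately post), t2 (+24 h),
t3 (+72 h):

- **CONT** multiplies the map by 1 + drift(t), drift = (0, 3.0, 6.7, 4.7) %
  — the incubation-related hydration increase seen in unimpacted controls.
- **LIMP** adds a band: A(t)·exp(−(d−0.5)²/2σ²) across the full width, with
  depth fraction d, σ = 0.18 of the tissue height, and amplitudes
  (0, 7.7, 18.7, 21.3) ms. The band sits in the transitional zone, parallel
  to the subchondral lamella, and is smooth in depth (partial-volume
  blurred); its parameters put the whole-sample relative change near
  +10/+23/+26 % at t1/t2/t3.
- **HIMP** adds a diffuse 2D Gaussian centred on the impaction site whose
  radius (σ from 0.16/0.20 to 0.28/0.32 of width/depth) and amplitude
  (0, 27, 30, 45 ms) grow with time, driving whole-sample changes near
  +15/+28/+58 %.

Signals use S0 = 1000 with Rician noise (magnitude of a complex Gaussian,
per-channel SD = S0/SNR) at SNR = 50 by default — no printed noise level
exists for the real acquisition, so SNR was chosen once such that fitted-T2
pixel scatter is small relative to the between-sample SDs above. Lesion
progression is a per-time-point parameterization, not a degradation model:
only qualitative lesion morphology is known, so amplitudes/radii are config
knobs with the defaults above. All randomness derives from one integer
seed (master seed → per-sample sub-seeds), making cohorts bit-reproducible.

What the phantom does **not** emulate: collagen-fibre orientation and the
magic-angle effect, B1/stimulated-echo artefacts, partial-volume mixing at
the cartilage–bone interface, 3D geometry, or any biophysical link between
impaction energy and T2. Passing tests therefore show that the *pipeline*
recovers and detects the modelled effects correctly — not that the effect
sizes themselves generalise to real tissue.

## Statistics

Within-group time effects use Friedman's test (mid-ranks, standard tie
correction; a fully tied table returns χ² = 0, p = 1) followed by Dunn's
z-based post-hoc on rank sums. Between-group effects per time point use the
tie-corrected Kruskal–Wallis test with Dunn's post-hoc on pooled ranks.
Relative changes Δx = (value_tx/value_t0 − 1)·100 % are computed per sample
(summaries report the mean of per-sample Δ, never the ratio of group means)
and compared by one-way ANOVA with Tukey's HSD — the mix of nonparametric
time/group tests with parametric Δ tests mirrors the field's practice and
is kept deliberately. α = 0.01 throughout, inclusive (p ≤ 0.01); Dunn
post-hoc p-values are unadjusted by default with Holm/Bonferroni available.
ANOVA with zero within-group variance everywhere is flagged undefined
rather than raised, so report assembly proceeds.

The suite checks the battery's calibration empirically: 500 all-control
cohorts (7/14/14 samples, one time point) give a Kruskal–Wallis type-I
error compatible with the nominal 1 %.

## Problem sizes

Default analyses use the full study design: 7/14/14 samples × 4 time
points (140 stacks of 19 × 71 × 12 voxels). A full simulate–fit–texture–
statistics run takes a few seconds; the Monte-Carlo recovery check uses
10 000 single-pixel replicates and the null calibration 500 single-time-
point cohorts.

## Design decisions that were genuinely open

- Fit algorithm (unstated in the underlying protocol): loglinear default for
  determinism and speed; nonlinear available and used for bias-sensitive
  checks.
- Quantization (unstated): L = 32, fixed 0–120 ms; rationale above.
- Orientation averaging (ambiguous): averages feature values, not matrices.
- Odd-height tie rule (unstated): ceil to superficial.
- Dunn adjustment (unstated): none by default, configurable.
- Control drift applies multiplicatively to controls only; impacted arms
  encode their whole change in the lesion fields.
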