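# Methods

This note documents the models implemented in `relaxovb`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not demonstrate.

## Two-site water-exchange model (`relaxovb.exchange`)

A voxel is modelled as two exchanging water pools — intravascular (blood)
and extravascular — with longitudinal relaxation quenching by the contrast
reagent (CR) confined to blood.  Inversion-recovery at the timescales used
here observes the long-lived eigenmode, so the apparent tissue rate R1t is
the smaller eigenvalue of

    [[R1b + k_b, -k_e], [-k_b, R1e + k_e]]

with blood→tissue rate k_b = 1/τ_b and the tissue→blood rate fixed by
detailed balance on the pool populations p = v_b/f_w and 1 − p, giving
k_e = p / (τ_b (1 − p)).  R1e is recovered from the pre-CR baseline by
inverting the same population mixture at [CR] = 0:
R1e = (R1t(0) − R1b(0)·p)/(1 − p).

Assumptions: monoexponential recovery per voxel; negligible CR
extravasation (K^trans ≈ 0); a single fixed τ_b and f_w for all voxels;
no T2/T2* contribution.  Limits used as correctness anchors: τ_b → 0
gives the population average p·R1b + (1−p)·R1e; τ_b → ∞ gives
min(R1b, R1e); v_b = 0 gives R1e.  Note that the apparent rate is
monotone in v_b only once the blood relaxes faster than tissue
(R1b ≥ R1e) — during washout this always holds; pre-CR it does not, which
is why sensitivity to v_b comes entirely from the post-CR samples.

Parameters and defaults:

| parameter | default | units | meaning |
|---|---|---|---|
| τ_b | 0.3 | s | mean intravascular water residence time (fixed) |
| f_w | 0.8 | – | plasma-restriction scaling of CR (fixed) |
| r1  | 3.3 | s⁻¹ mM⁻¹ | gadoteridol relaxivity at 7 T |
| h   | 0.40 | – | microvascular hematocrit |
| R1b(0) | 0.45 | s⁻¹ | pre-CR blood rate (arterial T1 ≈ 2.2 s at 7 T) |

f_w is dimensionless; a source that attaches seconds to it is treated as a
typographical slip, since Eq.-level dimensional analysis admits only a pure
number.  v_b is carried internally as a fraction and reported as mL/100 g
by multiplying by 100 (unit tissue density assumed).

**Fitting.**  τ_b and f_w are held fixed and v_b is the single free
parameter, estimated by trust-region least squares (the modern equivalent
of gradient-expansion/Levenberg–Marquardt), initial value 0.02, relative
tolerance 1e-10, ≤200 evaluations.  Residuals use only post-CR points; the
baseline enters solely through R1e.  Estimates are deliberately *not*
clipped: negative or implausibly large values are retained and removed
downstream by the physiological filter, so the exclusion statistics remain
meaningful.  Map-scale fitting (`fit_vb_many`) solves the same 1-D problem
for all voxels at once with a shared coarse grid (41 points on
[−0.1, 0.3]) plus vectorised golden-section refinement to ~1e-7; it agrees
with the scalar path to solver tolerance.  Weighted residuals were
considered and not used: per-point R1 uncertainties are nearly equal across
the washout, so weighting would change nothing at the cost of an extra
input.

## MPRAGE signal model and R1 mapping (`relaxovb.mprage`)

The variable-TI protocol acquires four segmented inversion-recovery
gradient-echo volumes per timepoint (TI = 300/1800/3200 ms and a
no-inversion condition; TR = 3500 ms, 6° constant flip angle).  Each cycle
is: inversion with efficiency β (Mz → (1−2β)Mz; β = 0 encodes "no
inversion"), free recovery, a train of `n_readouts` pulses spaced by
`echo_spacing` (each scaling Mz by cos α with T1 recovery between pulses),
then free recovery to TR.  TI is defined from the inversion to the
k-space-centre line under linear phase-encode ordering
(line `n_readouts // 2`).  Every step is an affine map of Mz, so the
periodic steady state is solved in closed form; an event-by-event Bloch
simulation is kept in the package as an independent oracle and the two
agree to < 1e-8 relative over randomised protocols.

The readout-train geometry defaults to 48 lines at 6 ms spacing — the
2-mm, 48-slice axial slab as the inner loop — which is the only reading
compatible with the timing constraint TI + train ≤ TR for the printed
TI = 3200 ms / TR = 3500 ms; a 176-line inner loop would occupy 1232 ms
and could not fit any of the printed inversion times.  Because the phantom
and the fitter share one protocol object, analyses are insensitive to this
choice by construction.

R1 fitting is a two-parameter (R1, M0) magnitude fit (polarity restoration
is not modelled), R1 bounded to [0.05, 10] s⁻¹.  M0 absorbs proton
density, T2* at the fixed TE, and receive gain.  The vectorised map fitter
profiles M0 out in closed form and solves the remaining 1-D problem by
coarse grid + golden-section, to ~1e-5 relative on noiseless data.
All-zero or constant voxels are flagged non-fits (NaN), never raised.
B1 inhomogeneity is not modelled or corrected.

Caveat: for CSF-like T1 (~4.2 s) the TI = 3200 ms condition lies near the
inversion null, and for blood-like post-CR R1 (~2–3 s⁻¹) all four signals
approach saturation; in both regimes magnitude fitting under noise leaves
a small (≲0.5%) bias in single-voxel R1 that averages down slowly.  ROI
means therefore carry their sampling error explicitly in the tests.

## Digital phantom (`relaxovb.phantom`)

The phantom reproduces the statistical and kinetic structure the analysis
assumes, not anatomy: an ellipsoidal brain of NAWM containing two
ellipsoidal lateral ventricles, a periventricular lesion rim (pWMH) hugging
the ventricle surface within 3 mm, six spherical deep lesions (dWMH,
radius 3.5 mm, ≥8 mm clear of the ventricle surface), and a
sagittal-sinus blood tube.  Default grid 96×96×48 at 1×1×2 mm — the
acquisition resolution, kept at desk scale.  Lesion radii guarantee the
three-consecutive-slice persistence rule by construction.

Study conditions (defaults): baseline T1 of 1454 ms (NAWM), 1608 ms
(dWMH), 1861 ms (pWMH), CSF R1 0.239 s⁻¹; true v_b 0.024 (NAWM, pWMH) and
0.018 (dWMH); plasma CR concentration 1.2 mM at injection decaying
monoexponentially with a 96-min half-life (gadoteridol's renal clearance
timescale; the plasma decay is a modelling choice and is parameterised);
linear CSF CR accumulation at 3.4 μM/hr (which reproduces a CSF ΔR1 of
0.0091 s⁻¹ over ~49 min at r1 = 3.3); image SNR 100; one pre-CR dataset
plus four post-CR datasets with midpoints 15/30/45/55 min.  Each dataset
is frozen at its temporal midpoint (no R1 drift within an acquisition).
Noise is zero-mean Gaussian with SD = mean foreground signal / SNR, added
per TI volume — Gaussian rather than Rician, matching the Monte Carlo
noise recipe the uncertainty analysis specifies; magnitude-bias effects of
true Rician noise are therefore *not* probed.  Other real-data features the
phantom does not emulate: B0/B1 fields, motion, registration error,
partial-volume mixing beyond a one-voxel ventricle surface layer, and
within-region biological heterogeneity of T1 and v_b (compartments are
piecewise constant).  Passing the loop-closure tests shows the estimator
chain is consistent and noise-stable under its own assumptions; it does not
certify accuracy against violations of those assumptions.

## Masks and ROIs (`relaxovb.masks`)

* **Seeded k-NN segmentation**: candidates are classified by the majority
  class of their k = 5 nearest seed voxels in a feature space of
  normalised intensity plus spatial coordinates (mm) down-weighted by
  0.02 per intensity SD — intensity dominates, space breaks ties, and the
  result is deterministic and seed-order invariant.  When two raters'
  masks are supplied, the consensus (intersection) is used.
* **Persistence filter**: a lesion component (26-connectivity) is kept only
  if it spans ≥3 consecutive slices along each of x, y and z; idempotent.
* **NAWM band**: WM voxels 15 ± 3 mm above the superior ventricular
  surface, measured along +z from the topmost ventricle voxel in each
  (x, y) column (full 3-D Euclidean distance available), lesions excluded.
* **Pixel overlap**: Jaccard ×100 by default (Dice optional) — the metric
  behind the ~80% inter-rater reproducibility figure is not uniquely
  determined, so the choice is documented rather than assumed.
* **CSF ROI**: pure-CSF voxels (fractional CSF volume = 1 within 1e-6) in
  the posterior horn of one lateral ventricle, ranked by distance from
  tissue interfaces, up to a 16 μL target volume.  At 2 μL voxels this is
  8 voxels; single-study permeability estimates are correspondingly noisy
  (SE ≈ 1 μM/hr at SNR 100) and the tests treat them as such.

## Pipeline statistics (`relaxovb.pipeline`, `relaxovb.stats`)

v_b values outside [0, 20] mL/100 g are excluded and the excluded fraction
reported.  Region means come from a fitted distribution: Shapiro–Wilk at
α = 0.05 (subsampled to 5000 voxels) accepts a Gaussian directly or after
log or square-root transformation (back-transformed means); otherwise
gamma and Weibull are fitted by maximum likelihood (location 0) and the
lower-AIC family's mean is reported.  Voxels are pooled per region class
rather than averaged per lesion.

SNR uses the signal-background method: noise σ is recovered from the mean
absolute background value via the half-normal correction
σ = mean(|bg|)·√(π/2) (the background of these real-valued synthetic
images is Gaussian; for magnitude images a Rayleigh convention would apply
and the `std` method is provided).  Monte Carlo uncertainty: R1 — Gaussian
noise with SD = signal/SNR per TI signal, refit, 1000 replicates; v_b —
each post-CR R1(t) perturbed uniformly within ±1 SD (Gaussian optional),
refit.  "Relative variance" is variance/mean² in percent (squared
coefficient of variation) throughout.

Group statistics: one-way within-subject ANOVA with
(k−1, (k−1)(n−1)) degrees of freedom (cross-checked against an independent
implementation in the tests); post-hoc paired t-tests with Hochberg's
step-up adjustment as the sequentially-rejective "modified Bonferroni"
(Holm optional); OLS regression with r²; outliers by Mahalanobis distance
against χ²(p, 0.975) and Cook's distance against 4/n, union flagged.
Water-fraction comparisons assume R1 inversely proportional to water
content, so the percent difference is 100·(T1_a/T1_b − 1).

## Ventricular permeability (`relaxovb.csf`)

CSF R1 is assumed linear in CSF CR concentration with the plasma
relaxivity r1 (no hematocrit factor applies in CSF).  The rate is the
least-squares slope of ROI-mean R1 versus time divided by r1 (an
endpoints method is provided; both agree exactly on affine series),
reported in μM/hr.  The measurement window is taken from the actual
acquisition midpoints; for the printed worked example the quoted
"50–55 min" window is ambiguous, so its midpoint is used and a ±10%
tolerance covers the ambiguity.

## Problem sizes used in validation

Unit tests run a down-scaled phantom (48×48×24) preserving all structural
rules; the end-to-end recovery check runs 20 seeded replicates of the full
default-grid (96×96×48) pipeline at SNR 100, ~11 s per replicate.  Monte
Carlo checks use the specified 1000 replicates.

## Known limitations

* τ_b and f_w are global constants; voxelwise exchange-time fitting is out
  of scope, and mis-set constants bias v_b multiplicatively.
* CR extravasation (nonzero K^trans) is not modelled; in periventricular
  tissue adjoining a leaky ependyma this assumption is the weakest.
* Magnitude R1 fitting near inversion nulls carries a small noise-rectification
  bias (see above); signed-polarity fitting is not implemented because the
  acquisition's polarity handling is not specified.
* The phantom's plasma decay and m0 (proton-density/gain) values are
  plausible choices, not measured quantities; analyses that cancel them
  (shared forward/inverse protocol) are insensitive to this.
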