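# Methods

`afablate` reimplements, as a tested pipeline, an in-silico study of deep
learning interpretability for atrial-fibrillation (AF) ablation therapy:
2D left-atrial (LA) tissue disks with fibrosis are generated synthetically,
AF is simulated on each disk with a Fenton–Karma monodomain model, three
catheter-ablation strategies are applied and judged, a multi-label CNN is
trained to predict each strategy's success from the tissue image alone, and
three feature-attribution methods are scored against the (hidden) ablation
lesions.

## Tissue disks

The simulation domain is a circular disk of tissue on a square pixel grid
(0.3 mm spacing, default 128 px ≈ 38 mm diameter) — a standardised 2D
"unfold" of the left atrium.  Four pulmonary-vein (PV) openings are
non-conducting discs placed on a ring at 72% of the disk radius; six fixed
layout variants ({small, large} radius × three angular offsets) stand in
for anatomical PV variability.  Since real LGE-MRI intensity maps are not
an input of this package, a spatially correlated Gaussian random field
(white noise smoothed so the autocorrelation falls to 1/e at the 4 mm
correlation length, min–max normalised) is used as the fibrosis-intensity
surrogate.  Thresholding the intensity yields the fibrotic/healthy label
grid; the threshold is drawn per disk from a configurable range, default
(0.5, 0.7), chosen so the cohort spans sparse to heavy (~50%) fibrotic
burden — the regime in which the augmentation scheme's mean fibrotic
fraction sits near its folding point.

Virtual-cohort augmentation blends all base intensity maps with one
uniform(0,1) scalar weight per map (the weight-normalised average stays in
[0,1]), applies a random non-empty subset of {translation, rotation, flip}
to the blended intensity (the PV geometry is never transformed), and draws
a fresh threshold and PV variant.  Averaging many maps compresses the
intensity distribution towards the middle, which would make a fixed
threshold range give all-or-nothing fibrosis; the blended map is therefore
min–max restretched inside the disk before the affine step (base maps
already span [0,1] by construction, so this applies the same convention to
both).  Everything is reproducible from a single seed via seed-sequence
spawning.

## Electrophysiology

The three-variable Fenton–Karma model (fast inward, slow outward and slow
inward currents; gates v and w) is solved in monodomain form

    du/dt = div(D grad u) − (Ifi + Iso + Isi),   Cm = 1,

with forward Euler and a 5-point Laplacian.  Face conductances are the
harmonic mean of the two adjacent diffusivities, so a zero-diffusivity
pixel (outside, PV, ablated lesion) closes its faces and zero-flux
boundaries appear without special-casing.  Healthy tissue has
D = 0.1 mm²/ms and fibrotic tissue D = 0.015 mm²/ms (ratio 0.15).  The
quoted values are sometimes printed in mm²/s; that literal reading gives a
space constant far below the 0.3 mm grid and no propagation at all, so the
mm²/ms convention is used (a converter is provided).  With the default
parameters the planar conduction velocity is ≈0.39 m/s in healthy tissue,
inside the physiological 0.3–1.0 m/s band.

### Parameter set

No published set of the three-variable catalogue sustains cross-field-
induced re-entry on a ~40 mm disk: their wavelengths (CV × APD ≈ 40–65 mm)
exceed the domain, so the induced wavefronts sweep out and extinguish.  The
default set is therefore an aggressively remodelled variant of catalogue
set 4 — the package's own calibration, selected by a systematic search
under four simultaneous constraints:

1. healthy-tissue CV in 0.3–1.0 m/s at D = 0.1 mm²/ms;
2. propagation survives in fibrotic tissue (D = 0.015) at dx = 0.3 mm,
   which requires a weak outward current during the upstroke (tau_r ≥ ~20 ms);
3. the standard cross-field S1–S2 protocol with S2 at 28 ms induces
   re-entry, which requires the S1 wake to be recovered at S2 time — an
   action potential of ~20 ms with fast v-gate recovery;
4. the induced activity is sustained ≥800 ms on a homogeneous
   100×100 sheet and ≥1500 ms on fibrotic disks.

The resulting constants (tau_d 0.2, tau_o 5, tau_r 20, tau_si 200,
tau_v+ 2.4, tau_v1− 4, tau_v2− 2, tau_w± unchanged, u_c 0.15, u_v 0.10)
compress the action potential to ~20 ms — far shorter than human atrial
myocardium, including remodelled persistent-AF tissue.  This is a
deliberate desk-scale regime: it preserves the study's structure (re-entry
sustained by the interplay of fibrosis, PV obstacles and boundaries;
termination or not under each lesion set) at a domain size and time scale
where hundreds of episodes are computable.  Times in the simulation should
be read as model time, not patient time.  The unmodified published sets 4
and 8 remain available (`FK_SET_4`, `FK_SET_8`).

At dx = 0.3 mm the lattice suppresses the fibrotic CV below the continuum
√(0.015/0.1) = 0.387 scaling (measured ratio ≈0.26); on refined calibration
strips the ratio converges (≈0.37 at dx = 0.1 mm, inside ±10% of √0.15).
CV calibration therefore runs at dx = 0.1 mm, dt = 0.02 ms.

### Protocol and termination

S1 excites a band at the left edge at t = 0 and S2 the bottom half-plane at
28 ms; both stimuli are impulsive u-resets to 1.0 applied only to excitable
(sub-threshold) pixels — forcing u on refractory tissue would artificially
extend its refractoriness.  The S1 band width default is 24 px: narrower
bands leave too thin a recovered wake at the printed S2 time and roughly
half the fibrotic disks then fail to induce (~95% induce at 24 px).
Episodes are judged terminated at the first time after which the maximum
u over tissue stays below u_act = 0.1 for a continuous 50 ms; runs stop
early on termination.  The stability guard enforces dt ≤ dx²/(4 D_max) and
dt ≤ min(tau)/2 before any run.

## Ablation strategies and labels

* **PVI** — a ring of ablated pixels (default width 2 px) around each PV.
* **FIBRO** — the one-pixel outer perimeter of every fibrotic patch of at
  least 9 px (speckle ignored).
* **ROTOR** — phase singularities are detected over the last 200 ms before
  ablation (analytic-signal phase of the mean-subtracted u series; ±2π
  winding on 2×2 plaquettes), single-linkage clustered at the lesion
  radius, and a filled disc (default radius 3 px = 0.9 mm) is placed at
  each cluster centroid.  Radius 2 px never terminated an episode in
  pilots, and larger discs tend to re-anchor re-entry; 3 px was the pilot
  optimum.  A run without detectable singularities yields an empty lesion
  set (the strategy then fails by non-termination).

Lesions are applied mid-episode (default 500 ms full scale, 400 ms scaled)
by zeroing the lesion pixels' diffusivity.  A strategy succeeds if the
episode terminates within the limit (2000 ms full scale, 1000 ms scaled)
and less than 40% of tissue pixels are ablated.  Disks whose baseline
episode is quiescent at ablation time are excluded as non-inducible.  The
per-disk baseline is simulated once and the three strategy runs continue
from its saved state, which is exactly equivalent to three full runs
because the lesions act only from the ablation time onward.

## Outcome classifier

A single-channel image encodes each disk (background/PV 0, healthy 0.5,
fibrotic 1.0).  The CNN has four 32-filter 3×3 same-padded convolution
blocks (ReLU, 2×2 max-pool) and linear layers of 2048, 128 and 3 units
with ReLU, dropout 0.8 between the 2048- and 128-unit layers, and a
sigmoid per class; "32 × 32 filters" is read as 32 filters of 3×3 (a 32×32
kernel is implausible at these image sizes), and a 128 px input makes the
flattened conv output exactly 2048, consistent with the first linear
width.  The loss is the multi-label mean squared error Σᵢ(ŷᵢ−yᵢ)²/N (the
per-class squared error; a signed mean would not be a loss).  Training
uses Adam at lr 1e-4, batch 16, keeping the epoch state with the lowest
validation loss.  Evaluation follows a fixed hold-out plus fold-rotation
protocol: each fold serves once as the validation set, every fold's model
is scored on the same hold-out, and means ± sd are reported per class for
AUC, recall, precision and F1 (threshold 0.5; an all-negative prediction
reports precision 1.0 by the zero-false-positive convention).  The network
and its backpropagation are implemented in numpy; training is bitwise
reproducible from the seed under a fixed BLAS threading configuration.

Two initialisation choices matter at small cohort sizes.  Inputs are
centred at the healthy-tissue level (x − 0.5) so the image's DC component
(which tracks fibrotic burden) does not dominate undertrained scores, and
the output bias starts at the logit of each class's training base rate.
The latter interacts with checkpoint selection: with a freshly initialised
head, the first epochs lower the validation MSE merely by drifting towards
the prior, and the minimum-validation-loss rule then selects a
non-discriminative early epoch.  Starting at the prior removes that
degenerate minimum, so selection favours epochs that actually rank
outcomes.  Checkpoint selection itself keeps the latest epoch whose
validation loss lies within a 2% relative tolerance of the minimum
(`selection_tolerance`; 0 restores the strict argmin): with ~20-disk
validation folds, sub-0.1% loss differences between an epoch-3 and an
epoch-33 state are numerically meaningless, and at equal validation
performance the longer-trained state generalises better.  The
label-shuffled control is averaged over three independent permutations,
each trained with the real model's budget, because a single shuffle's AUC
on a small hold-out has a standard deviation near 0.1.

## Interpretability

GradCAM weights each channel of a conv block by the global-average-pooled
gradient of the class logit (pre-sigmoid, so maps are invariant to output
squashing) and rectifies the weighted sum.  The tap defaults to the last
conv block; at the reference 128 px input that block's maps are 8×8.  At
the scaled 64 px input the last block is only 4×4 — too coarse to localise
lesion-scale structure — so the scaled configuration taps block 3, whose
8×8 maps match the reference resolution.  Occlusion slides a
16×16 patch with stride 8, replacing it with the background value, and
assigns each pixel the mean class-score drop over its covering patches.
LIME segments the input into ~49 grid superpixels, samples binary on/off
perturbations, weights them by exp(−d²/0.25²) on the normalised L2
distance to the unperturbed point, and fits a weighted ridge surrogate
whose coefficients are broadcast to pixels.

Maps are resampled to the disk grid and thresholded strictly above
factor × (mean attribution over tissue pixels), factors {0.75, 1.0, 1.25};
background pixels are excluded from the mean because their zeros would
deflate it and inflate every region.  Regions are scored against each
strategy's lesions with IoU, lesion percentage and NAT percentage
(fraction of the region on tissue that is neither lesion nor fibrosis).
Empty-denominator cases are NaN, excluded pairwise downstream.
Population-level maps are per-item min–max normalised, then averaged.

## Statistics

Pairwise method differences of per-disk metrics use the Wilcoxon
signed-rank test (zero differences dropped; exact null for n ≤ 25 without
ties, normal approximation otherwise) at the Bonferroni-corrected
alpha 0.05/3 ≈ 0.017 for the three method pairs.  Per-fold AUC vectors are
compared with a one-sided two-sample Welch t-test.

## Scaled study conditions

The full-scale protocol (dt 0.01 ms, 2000 ms episodes, 100 epochs,
5 folds, 264-disk cohort) is available through the same configuration
objects.  The test suite and `scripts/acceptance.py` run the package's
scaled conditions, fixed in `StudyConfig.scaled()`: 38 base + 74 synthetic
128 px disks, dt 0.1 ms, ablation at 400 ms, 1000 ms episode limit, 64 px
model input, 40 epochs, 3 folds, 28 hold-out disks, attribution on 8
hold-out disks with 150 LIME samples.  A label-shuffled control with the
same training budget accompanies the real model.

## What the synthetic data does and does not show

The generator reproduces the patchy morphology and burden range of
fibrotic LA tissue and the PV anatomy variants, but not real LGE-MRI
intensity statistics, wall-thickness effects, fibre anisotropy or true
atrial geometry; the electrophysiology is a phenomenological desk-scale
regime.  Passing tests therefore demonstrate that the pipeline's
machinery — induction, strategy planning, the success rule, learnability
of outcomes from structure, and attribution scoring — behaves correctly
and reproduces the study's qualitative structure (fibrosis-based ablation
most predictable; attribution regions aligning with lesions), not that the
numerical rates transfer to patients.

## Numerical choices and edge cases

Ties at the informative-region threshold are excluded (strict >).  The
quiescent equilibrium of u is slightly positive (residual slow-inward
current at u = 0); `FKParams.rest_u()` solves it and the rest state is an
exact fixed point of the stepper.  Phase is undefined (NaN) where the
analytic-signal amplitude is below 1e-3; plaquettes touching NaN are
skipped.  A phase defect lying exactly on a grid node splits its winding
across four plaquettes; detection and the test oracle agree on this
convention.  Non-inducible disks, empty lesion sets, empty informative
regions and single-class AUC are all reported as missing rather than
silently dropped.

## Known limitations

ROTOR termination rates are well below the original study's (small discs
at micro-re-entry cores rarely extinguish activity in this regime), so the
ROTOR label is the most imbalanced.  The lattice CV ratio at study
resolution underestimates the continuum √D scaling.  Hold-out sets of ~24
disks give AUC estimates with sizeable sampling noise; the acceptance
checks use margins (shuffled-label control) rather than point targets.
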