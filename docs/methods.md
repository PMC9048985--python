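# Methods

`dcepk` implements a complete quantitative DCE-MRI vascular-permeability
workflow for small-animal brain imaging, together with a convolutional
surrogate that predicts permeability maps directly from the dynamic
images, and a digital tumor phantom that makes every stage testable
without animal data. This note records the models, the parameters that
matter, the numerical choices, and the limits of what the synthetic
experiments demonstrate.

## Signal model

Dynamic and T1-mapping scans are modeled by the steady-state spoiled
gradient-echo (SPGR/FLASH) equation

    S = M0 · (1 − E) sin θ / (1 − E cos θ),    E = exp(−TR/T1).

**VFA T1 mapping.** The multi-flip-angle acquisition is linearized per
voxel: X_i = SI_i / tan α_i, Y_i = SI_i / sin α_i lie on a line with
slope Sp = exp(−TR/T10), fitted by ordinary least squares, giving
T10 = −TR / ln Sp. Voxels with Sp outside (0, 1) (noise, air, degenerate
signals) are flagged invalid and carried as NaN with a boolean quality
mask; they are never clamped, because silently clamping T10 would bias
every downstream concentration and kinetic estimate.

**Concentration conversion.** Gadolinium shortens T1 through the
fast-exchange relation 1/T1(t) = 1/T10 + r1·Ct(t) with relaxivity
r1 = 3.11 s⁻¹mM⁻¹ (gadopentetate at 7 T, the default; configurable).
The voxel's equilibrium magnetization M0 is back-computed from the
pre-contrast baseline — the mean of the first `baseline_frames`
(default 5) dynamics — and the fitted T10; each frame's signal is then
inverted in closed form for T1(t) (the SPGR equation is linear in E).
Frames whose signal ratio leaves E outside (0, 1) are non-invertible
(possible at very high concentration or strong noise) and are flagged,
not extrapolated. The forward conversion (concentration → signal) is
the exact inverse and drives the phantom simulator; the pair
round-trips to ~1e-15 in double precision.

Default acquisition constants mirror a 7 T small-animal protocol:
dynamic TR 43 ms at flip angle 30°, VFA TR 100 ms at angles
5/10/20/35°, frame spacing dt = 10.4 s. The frame spacing is an
inference from a ~7-minute scan retaining 40 dynamics and is flagged as
such in the configuration docs; all constants are overridable.

## Arterial input function

Individual AIF measurement is impractical in mice, so the plasma curve
is a population-averaged bi-exponential

    Cp(t) = a·e^(−c1·(t−t0)) + b·e^(−c2·(t−t0))  for t ≥ t0, else 0,

with fast (distribution) rate c1 > slow (clearance) rate c2 > 0,
amplitudes in mM and rates in min⁻¹. The shipped default is the
classical gadopentetate population parameter set scaled to a
0.1 mmol/kg dose (a = 0.399 mM, b = 0.478 mM, c1 = 0.144 min⁻¹,
c2 = 0.0111 min⁻¹). These are deliberately explicit configuration
inputs rather than constants buried in code: they are placeholders of
the right form and magnitude, and users analyzing real data should
substitute the population AIF appropriate to their species, agent and
dose. t0 defaults to the detected contrast-arrival frame times the
frame spacing.

## Kinetic models and inversion

The tissue models are the classical Tofts model and its extended form:

    Tofts:     Ct(t) = Ktrans ∫₀ᵗ Cp(τ) e^(−Kep (t−τ)) dτ
    Ex-Tofts:  Ct(t) = Vp·Cp(t) + Ktrans ∫₀ᵗ Cp(τ) e^(−Kep (t−τ)) dτ

with Ve = Ktrans/Kep derived afterwards. For a bi-exponential AIF the
convolution has the closed form Σᵢ ampᵢ/(Kep−cᵢ)·(e^(−cᵢu) − e^(−Kep u));
the removable singularity at Kep = cᵢ is evaluated by a first-order
series around the analytic limit u·e^(−cᵢu) (switch threshold
|Kep−cᵢ| < 1e-8, continuous to ~1e-6). Model evaluation and its
Jacobian are therefore analytic, and both are verified against
trapezoidal quadrature at 100× oversampling (agreement ≤ 1e-4
relative).

Inversion is bounded trust-region-reflective nonlinear least squares
per voxel over (Ktrans, Kep[, Vp]), fitted directly in that
parameterization so Ve is a derived ratio. Choices, all configurable:

* bounds Ktrans ∈ [0, 5] min⁻¹, Kep ∈ [1e-3, 10] min⁻¹, Vp ∈ [0, 1] —
  generous relative to reported rodent brain-tumor values, so genuine
  estimates never sit on a bound (bound-hugging voxels are flagged);
* fixed initialization (0.05, 0.5, 0.02), with an optional 3×3(×3)
  multistart grid for high-noise data and an optional linear
  least-squares warm start (the integral form of the tissue ODE,
  solvable by OLS) that roughly halves fitting time without changing
  the solution;
* cost tolerance 1e-10, analytic Jacobian, pre-arrival frames excluded
  from the residual.

Fits are voxelwise independent with deterministic options, so maps do
not depend on the voxel visiting order and reruns are bit-identical.
Noise-free forward–inverse round trips recover parameters to ~1e-11
relative across the tested grid (Ktrans 0.01–0.5, Kep 0.1–2, Vp 0–0.1).

## Digital phantom

The phantom emulates the geometry of a multi-slice small-animal brain
study: an elliptical brain region of low-permeability background tissue
(intact blood–brain barrier) containing one or more elliptical
hyperpermeable lesions, simulated at 64×64 (desk scale, default) or
128×128 per slice, 40 dynamics, with contrast arrival at frame 5.

Intratumoral heterogeneity is produced by a seeded Gaussian random
field smoothed at a configurable correlation length and rank-mapped
onto the configured parameter range — the marginal distribution over
lesion voxels is uniform on the range by construction (testable by a
KS test) while remaining spatially smooth. Texture scale 0 degenerates
to piecewise-constant midpoint maps. Non-enhancing lesions
(Ktrans = 0, emulating an intact blood–tumor barrier) are supported.

Default tissue ranges (min⁻¹ / fractions): background Ktrans
0.005–0.02, Kep 0.1–0.3, Vp 0.005–0.015 at T10 = 1.9 s; lesion Ktrans
0.05–0.3, Kep 0.3–1.2, Vp 0.01–0.08 at T10 = 2.2 s. The background
Ktrans is kept slightly above zero so that noise-free closure tests
can measure relative error everywhere; at exactly zero transfer Kep is
unidentifiable.

Forward simulation chains the extended-Tofts model, the SPGR signal
equation at the voxel's T10, and noise: Rician by default (magnitude
MRI data; its low-SNR positive bias is tested at SNR 2), Gaussian for
analytic checks. The noise level is specified in signal units; a
helper converts a concentration-denominated level (e.g. 0.01 mM) into
signal units via the baseline sensitivity dS/dC at C = 0. A matching
VFA series is simulated with the same noise model. Cohorts of
"subjects" are produced by deterministically re-seeding per subject
and randomizing lesion count (1–2), position and size; everything is
bit-reproducible from the master seed.

What the phantom does **not** emulate: anatomy (no atlas), motion and
susceptibility artifacts, B1 inhomogeneity, water-exchange effects,
partial volume at lesion rims, and spatially correlated physiological
noise. Passing the synthetic tests therefore certifies the numerics
and the learning machinery, not robustness to those real-data effects.

## Dual-pathway convolutional surrogate

The surrogate treats parameter estimation as image-to-image
regression: input is one slice's normalized 40-frame dynamic series
(40 channels), output a single-parameter map of the same in-plane
size. Composition:

* stem: per-channel low-level feature extraction, implemented as a
  depthwise 4×4 convolution followed by a 1×1 pointwise projection to
  128 filters (a literal reading of "2-D filters applied to each
  channel individually"); a standard-convolution stem is available via
  `stem_mode="standard"`;
* local pathway: three plain 4×4 convolutions (128 filters, ReLU),
  resolving fine intratumoral detail;
* global pathway: three 4×4 convolutions dilated by 2, 4, 8 (128
  filters, ReLU), growing the receptive field to capture context and
  overall structure;
* the pathway outputs are concatenated (256 channels) and fed to a
  per-pixel fully connected head realized as 1×1 convolutions of
  1024/512/128/1 nodes, ReLU after every layer except the final
  regression output.

All convolutions are zero-padded size-preserving (even kernels pad one
extra row/column after). The composed stack is 22 module layers
(12 convolutions + 10 ReLUs); counting the input and regression output
layers in the style of some frameworks gives the colloquial
"24-layer" figure — the composition above, auditable programmatically
via `architecture_summary`, is the contract.

**Preprocessing.** Optional 3-D Gaussian smoothing (default off for
synthetic data, σ configurable), truncation to the first 40 dynamics,
masking of extra-cerebral voxels, then per-plane standardization: each
(slice, frame) plane is scaled to zero mean and unit variance over its
masked voxels (constant planes map to zero). Per-plane rather than
per-channel normalization was chosen because each temporal frame of
each slice has its own intensity scale.

**Training.** Masked per-voxel mean squared error (MSE is the standard
regression loss; the target's loss is not otherwise specified by the
protocol) plus an L2 penalty λ/2·‖w‖² on convolution weights (biases
exempt), optimized by Adam at learning rate 1e-4 with λ = 1e-4, up to
600 epochs at minibatch 20 full scale. Validation loss is checked
every 2 training iterations; training stops after 10 consecutive
non-improving checks and the best-validation weights are restored.
Targets are standardized over the training masked voxels (undone at
prediction) so the fixed learning rate behaves uniformly across
parameters with very different magnitudes (Ktrans ~0.1 vs Vp ~0.03),
and the final regression layer is zero-initialized so the network's
initial prediction is exactly the (normalized) target mean — on a
short schedule this removes the run-to-run variance a randomly
initialized head would inject and guarantees the optimizer descends
from the constant-mean-predictor baseline.
One master seed fans out to fold assignment, weight initialization and
batch shuffling; training is bit-reproducible.

The layers, backward passes and optimizer are implemented directly in
NumPy (convolution as a single im2col GEMM per layer), which keeps the
package dependency-light and the computation fully deterministic on
CPU; gradients are verified against finite differences in the tests.

**Cross-validation.** Leave-one-subject-out rotation: each subject is
held out once for testing; one random slice of every remaining subject
forms the validation set (20% at the full 6-subject × 5-slice
geometry) and the rest train. Held-out predictions are evaluated per
fold and pooled across folds for the ensemble analysis.

**Desk-scale profile.** The default synthetic study runs at 64×64 with
2 slices per subject, a reduced network (32 stem/pathway filters, head
256/128/64/1), minibatch 4 and at most 60 epochs. These sizes were
chosen so a complete 6-fold study (phantom generation, target fitting,
training, evaluation) finishes in minutes on one CPU core; the
full-scale architecture and protocol remain available through the
configuration.

## Evaluation

Agreement between predicted and target maps over a region of interest:
RMSE; nRMSE = RMSE / SD(target) using the sample (n−1) SD (the
convention is configurable in analysis code; sample SD is the
package's documented choice), so nRMSE < 1 means the prediction beats
a constant mean predictor; ordinary least-squares regression of
prediction on target (target on the x-axis) with the two-sided p-value
for a nonzero slope; Bland–Altman bias and 95% limits of agreement
(bias ± 1.96·SD of differences). A constant target yields an nRMSE of
NaN rather than a division by zero. The intratumoral region is the
lesion mask; the peripheral rim is the lesion minus its one-voxel
8-connected erosion, computed per slice in 2-D.

## Determinism and I/O

All randomness flows through seeded `numpy` generators. Pipeline runs
write a manifest (resolved configuration, package version, seed) and
produce byte-identical CSV/NIfTI outputs on rerun; NIfTI is written
uncompressed to keep outputs byte-comparable. Images use dimension
order (row, col, frame-or-angle, slice) with 0-based voxel indices;
affines are carried through unchanged. Raw scanner formats (Bruker
2dseq) and co-registration are out of scope; the pipeline ingests
converted NIfTI volumes.

## Known limitations

* The population AIF defaults are human-derived placeholders; mouse
  plasma kinetics are substantially faster, and quantitative accuracy
  on real mouse data requires a species-appropriate AIF.
* No B1 correction, water-exchange modeling, or T2* correction; at
  high concentrations the SPGR inversion flags rather than corrects
  non-invertible frames.
* The CNN study at desk scale demonstrates the protocol (nRMSE < 1 on
  held-out subjects) on synthetic data whose signal-to-parameter
  mapping is, by construction, realizable by the model family; it does
  not establish performance on real tumors.
* Training time grows quadratically with in-plane size and filter
  count on CPU; the full 128×128/128-filter configuration is provided
  for completeness but is slow without further optimization.
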