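# dcepk

Quantitative vascular-permeability mapping from dynamic
contrast-enhanced (DCE) MRI of small-animal brain tumors — and a
convolutional surrogate that predicts the permeability maps directly
from the dynamic images, skipping the conventional modeling chain.

## The problem

DCE MRI tracks a gadolinium bolus through tissue with a series of
T1-weighted images. Fitting a pharmacokinetic (PK) model to each
voxel's concentration curve yields microvascular parameters — the
transfer constant Ktrans (min⁻¹), the efflux rate Kep (min⁻¹), the
plasma volume fraction Vp and the extravascular extracellular volume
fraction Ve = Ktrans/Kep — that quantify blood–brain-barrier
disruption in brain tumors. The conventional chain is accurate but
slow and operator-dependent: it needs a separate variable-flip-angle
(VFA) T1-mapping scan, identification of the contrast-arrival frame,
an arterial input function (AIF), and thousands of nonlinear
least-squares fits per slice.

`dcepk` implements both routes:

1. **Conventional PK modeling.** SPGR signal physics, VFA T10 mapping
   (T10 = −TR/ln Sp from the linearized multi-angle fit),
   signal-to-concentration conversion via 1/T1(t) = 1/T10 + r1·Ct(t),
   a population bi-exponential AIF
   Cp(t) = a·e^(−c1 t) + b·e^(−c2 t), and voxelwise bounded NLLS
   inversion of the Tofts model
   Ct(t) = Ktrans ∫₀ᵗ Cp(τ)e^(−Kep(t−τ))dτ and its extended form
   Ct(t) = Vp·Cp(t) + Ktrans ∫₀ᵗ Cp(τ)e^(−Kep(t−τ))dτ, with
   closed-form model and Jacobian evaluation.
2. **CNN surrogate.** A dual-pathway convolutional network (a local
   pathway of plain 4×4 convolutions and a global pathway dilated by
   2/4/8, concatenated into a per-pixel fully connected head of
   1024/512/128/1 nodes) maps the normalized 40-frame dynamic series
   of a slice directly to one PK parameter map, trained
   leave-one-subject-out against the conventional maps.

A seeded **digital tumor phantom** (heterogeneous hyperpermeable
lesions on a low-permeability background, Rician noise, matching VFA
series) generates ground-truth data for testing both routes and
training the network. Everything is deterministic given the seeds.

## Worked example

Simulate a noise-free phantom subject, fit Tofts maps, and compare the
fitted Ktrans map against the phantom's ground truth inside the
lesion:

```bash
cat > config.yaml <<EOF
phantom:
  shape: [24, 24]
  n_slices: 1
  brain_radii: [9.5, 9.5]
  lesions:
    - {center: [12, 12], radii: [4, 4]}
  noise_sigma: 0.0
  seed: 7
n_subjects: 1
seed: 7
EOF
dcepk make-phantom --config config.yaml --out phantom/
# -> wrote 1 subject(s) under phantom/

printf 'paths: {subject: phantom/subject00}\nmodels: [tofts]\n' > fit.yaml
dcepk fit-pk --config fit.yaml --out maps/
# -> tofts: convergence 1.000

dcepk evaluate --pred maps/tofts_ktrans.nii \
               --target phantom/subject00/truth_ktrans.nii \
               --mask phantom/subject00/lesion_mask.nii --out eval/
# -> RMSE 0.1113  nRMSE 1.527  bias 0.09649
```

The lesion's true Ktrans spans 0.05–0.3 min⁻¹. The phantom simulates
the extended-Tofts model, so fitting the classical Tofts model — which
has no plasma term — forces the intravascular signal into an inflated
Ktrans: a systematic +0.096 min⁻¹ bias and nRMSE 1.53 even on
noise-free data. Refitting with `models: [extofts]` recovers the truth
to numerical precision:

```
RMSE 1.034e-13  nRMSE 0.000  bias 5.872e-15
```

The `maps/` directory also holds per-voxel diagnostics
(`tofts_diagnostics.csv`) and a manifest sufficient to reproduce the
run bit-identically.

The same pipeline scales to the full synthetic cohort study:
`dcepk make-phantom` with more subjects, `dcepk train-cnn` for the
leave-one-subject-out network training, `dcepk predict-cnn` for
inference from a checkpoint.

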