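"""Digital tumor phantom: ground-truth PK maps and simulated DCE/VFA scans.

The phantom emulates a small-animal brain DCE study: an elliptical "brain"
of low-permeability background tissue (intact blood-brain barrier,
Ktrans near zero) containing one or more hyperpermeable elliptical
lesions with smoothly varying intratumoral parameters.  Heterogeneity is
produced by a seeded Gaussian random field, spatially smoothed and then
rank-mapped onto the configured parameter range, so lesion histograms are
uniform over the range by construction while remaining spatially
correlated.

A full simulated study chains the forward physics: extended-Tofts tissue
curves from the truth maps and a population AIF, conversion to SPGR
signal via the T10 field, and Rician (default, MRI magnitude data) or
Gaussian noise.  A matching multi-flip-angle series is simulated for T1
mapping.  Everything is bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .aif import AIFParams
from .pk_models import PKMaps, extofts_forward_map
from .signal_model import (AcquisitionParams, ConcentrationSeries,
                           DynamicSeries, T1Map, VFASeries,
                           concentration_to_signal, spgr_signal)

__all__ = ["LesionSpec", "PhantomSpec", "PhantomStudy", "make_truth_maps",
           "simulate_study", "make_cohort", "signal_sigma_for_concentration"]


@dataclass
class LesionSpec:
    """One elliptical lesion: center/radii in voxels, parameter ranges in
    min^-1 (ktrans, kep) and fractions (vp); ``texture_scale`` is the
    smoothing length (voxels) of the intratumoral random field, 0 meaning
    piecewise-constant at the range midpoints; ``enhancing=False`` models
    an intact blood-tumor barrier (Ktrans = 0, Vp at background level)."""

    center: tuple = (32, 32)
    radii: tuple = (8, 8)
    ktrans_range: tuple = (0.05, 0.3)
    kep_range: tuple = (0.3, 1.2)
    vp_range: tuple = (0.01, 0.08)
    texture_scale: float = 3.0
    slices: tuple | None = None
    enhancing: bool = True


@dataclass
class PhantomSpec:
    """Study geometry, tissue parameter ranges, noise model, and seed."""

    shape: tuple = (64, 64)
    n_slices: int = 2
    n_dynamics: int = 40
    dt: float = 10.4
    arrival_index: int = 5
    lesions: tuple = (LesionSpec(),)
    background_ktrans: tuple = (0.005, 0.02)
    background_kep: tuple = (0.1, 0.3)
    background_vp: tuple = (0.005, 0.015)
    background_texture: float = 4.0
    t10_background: float = 1.9
    t10_lesion: float = 2.2
    m0: float = 1000.0
    brain_radii: tuple | None = None
    noise_model: str = "rician"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if self.n_dynamics < 1 or self.n_slices < 1:
            raise ValueError("need at least one frame and one slice")
        if not (0 <= self.arrival_index < self.n_dynamics):
            raise ValueError("arrival_index out of range")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_dynamics) * self.dt


@dataclass
class PhantomStudy:
    """Bundle returned by :func:`simulate_study`."""

    dynamic: DynamicSeries
    vfa: VFASeries
    truth: PKMaps
    concentration: ConcentrationSeries
    t10: np.ndarray
    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    spec: PhantomSpec


def _ellipse_mask(shape, center, radii):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _textured_field(rng, region_mask, lo, hi, scale):
    """Spatially correlated field on ``region_mask`` spanning [lo, hi].

    A smoothed normal field is rank-transformed to a uniform distribution
    over the range, preserving spatial correlation."""
    n = int(region_mask.sum())
    if n == 0:
        return np.zeros(0)
    if scale <= 0 or lo == hi:
        return np.full(n, 0.5 * (lo + hi))
    noise = rng.standard_normal(region_mask.shape)
    smooth = gaussian_filter(noise, sigma=scale)[region_mask]
    ranks = np.argsort(np.argsort(smooth, kind="stable"), kind="stable")
    u = (ranks + 0.5) / n
    return lo + u * (hi - lo)


def make_truth_maps(spec: PhantomSpec):
    """Ground-truth extended-Tofts maps plus brain and lesion masks.

    Returns ``(PKMaps, brain_mask, lesion_mask)`` with 3-D
    (row, col, slice) arrays.  Raises if lesions overlap each other or
    leave the brain mask.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    S = spec.n_slices
    brad = spec.brain_radii or (0.41 * H, 0.41 * W)
    brain2d = _ellipse_mask((H, W), (H / 2 - 0.5, W / 2 - 0.5), brad)
    brain = np.repeat(brain2d[:, :, np.newaxis], S, axis=2)

    ktrans = np.full((H, W, S), np.nan)
    kep = np.full((H, W, S), np.nan)
    vp = np.full((H, W, S), np.nan)
    lesion_mask = np.zeros((H, W, S), dtype=bool)

    for s in range(S):
        b2 = brain[:, :, s]
        ktrans[b2, s] = _textured_field(rng, b2, *spec.background_ktrans,
                                        spec.background_texture)
        kep[b2, s] = _textured_field(rng, b2, *spec.background_kep,
                                     spec.background_texture)
        vp[b2, s] = _textured_field(rng, b2, *spec.background_vp,
                                    spec.background_texture)

    for lesion in spec.lesions:
        l2 = _ellipse_mask((H, W), lesion.center, lesion.radii)
        slices = lesion.slices if lesion.slices is not None else tuple(range(S))
        for s in slices:
            if not np.all(brain[:, :, s][l2]):
                raise ValueError("lesion extends outside the brain mask")
            if np.any(lesion_mask[:, :, s] & l2):
                raise ValueError("lesions overlap")
            lesion_mask[:, :, s] |= l2
            if lesion.enhancing:
                ktrans[l2, s] = _textured_field(rng, l2, *lesion.ktrans_range,
                                                lesion.texture_scale)
                kep[l2, s] = _textured_field(rng, l2, *lesion.kep_range,
                                             lesion.texture_scale)
                vp[l2, s] = _textured_field(rng, l2, *lesion.vp_range,
                                            lesion.texture_scale)
            else:
                ktrans[l2, s] = 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        ve = ktrans / kep
    truth = PKMaps(ktrans=ktrans, kep=kep, ve=ve, vp=vp, model_tag="extofts",
                   mask=brain)
    return truth, brain, lesion_mask


def _t10_field(spec: PhantomSpec, brain, lesion_mask):
    t10 = np.full(brain.shape, np.nan)
    t10[brain] = spec.t10_background
    t10[lesion_mask] = spec.t10_lesion
    return t10


def _add_noise(rng, signal, model, sigma):
    if sigma == 0:
        return signal
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, signal.shape)
    # Rician: magnitude of a complex signal with iid Gaussian channel noise
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def simulate_study(spec: PhantomSpec, aif: AIFParams,
                   acq: AcquisitionParams) -> PhantomStudy:
    """Forward-simulate a full DCE study from a phantom specification.

    Chain: truth maps -> extended-Tofts concentration curves (AIF shifted
    to the arrival frame) -> SPGR dynamic signal at the T10 field -> noise;
    plus a matching VFA series.  Outside the brain the signal is pure
    noise (air).
    """
    truth, brain, lesion_mask = make_truth_maps(spec)
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(2 ** 31))
    time = spec.time
    aif_t = replace(aif, t0=spec.arrival_index * spec.dt)
    H, W = spec.shape
    S = spec.n_slices
    T = spec.n_dynamics

    ct = np.zeros((H, W, T, S))
    flat = brain.reshape(-1)
    kt = truth.ktrans.reshape(-1)[flat]
    ke = truth.kep.reshape(-1)[flat]
    vp = truth.vp.reshape(-1)[flat]
    curves = extofts_forward_map(kt, ke, vp, aif_t, time)  # (n_vox, T)
    ct_flat = np.zeros((H * W * S, T))
    ct_flat[flat] = curves
    ct = ct_flat.reshape(H, W, S, T).transpose(0, 1, 3, 2)  # (H, W, T, S)

    t10 = _t10_field(spec, brain, lesion_mask)
    t10_safe = np.where(brain, t10, spec.t10_background)
    t1map = T1Map(t10=t10_safe, slope=np.exp(-acq.vfa_tr / t10_safe),
                  mask=brain, valid=np.ones_like(brain, dtype=bool))
    conc = ConcentrationSeries(ct=ct, time=time, mask=brain,
                               arrival_index=spec.arrival_index)
    clean = concentration_to_signal(conc, t1map, acq, m0=spec.m0)
    signal = np.where(brain[:, :, np.newaxis, :], clean.signal, 0.0)
    signal = _add_noise(rng, signal, spec.noise_model, spec.noise_sigma)

    dyn = DynamicSeries(signal=signal, time=time, mask=brain,
                        arrival_index=spec.arrival_index)
    dyn.s0 = dyn.compute_s0(acq.baseline_frames)

    vfa_clean = np.stack([np.where(brain, spgr_signal(t10_safe, spec.m0, acq,
                                                      tr=acq.vfa_tr, flip_angle=a), 0.0)
                          for a in acq.vfa_angles], axis=-1)
    vfa_sig = _add_noise(rng, vfa_clean, spec.noise_model, spec.noise_sigma)
    vfa = VFASeries(signals=vfa_sig, angles=acq.vfa_angles, mask=brain)

    return PhantomStudy(dynamic=dyn, vfa=vfa, truth=truth, concentration=conc,
                        t10=t10, brain_mask=brain, lesion_mask=lesion_mask,
                        spec=spec)


def signal_sigma_for_concentration(spec: PhantomSpec, acq: AcquisitionParams,
                                   sigma_mm: float) -> float:
    """Signal-domain noise SD equivalent to ``sigma_mm`` (mM) of concentration.

    Uses the baseline sensitivity dS/dC at C = 0 for the background T10,
    so a stated concentration-domain noise level can be realized on the
    simulated magnitude signal.
    """
    d = 1e-4
    r1_0 = 1.0 / spec.t10_background
    s = [spec.m0 * _spgr_frac_r1(r1_0 + acq.r1 * c, acq) for c in (0.0, d)]
    return sigma_mm * (s[1] - s[0]) / d


def _spgr_frac_r1(r1, acq: AcquisitionParams):
    from .signal_model import spgr_fraction
    return spgr_fraction(1.0 / r1, acq.tr, acq.flip_angle)


def _subject_spec(rng: np.random.Generator, base: PhantomSpec) -> PhantomSpec:
    """Randomize lesion geometry for one subject around the base spec."""
    H, W = base.shape
    n_lesions = int(rng.integers(1, 3))
    lesions = []
    proto = base.lesions[0] if base.lesions else LesionSpec()
    for _ in range(n_lesions):
        for _attempt in range(50):
            radii = tuple(rng.uniform(0.09, 0.17) * np.array([H, W]))
            center = (rng.uniform(0.30, 0.70) * H, rng.uniform(0.30, 0.70) * W)
            cand = replace(proto, center=center, radii=radii)
            test = replace(base, lesions=tuple(lesions) + (cand,),
                           seed=int(rng.integers(2 ** 31)))
            try:
                make_truth_maps(test)
            except ValueError:
                continue
            lesions.append(cand)
            break
    return replace(base, lesions=tuple(lesions), seed=int(rng.integers(2 ** 31)))


def make_cohort(n_subjects: int, master_seed: int, base: PhantomSpec,
                aif: AIFParams, acq: AcquisitionParams) -> list:
    """Simulate ``n_subjects`` independent phantom subjects.

    Each subject gets its own randomized lesion layout and noise
    realization, all derived deterministically from ``master_seed``.
    """
    rng = np.random.default_rng(master_seed)
    return [simulate_study(_subject_spec(rng, base), aif, acq)
            for _ in range(n_subjects)]
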