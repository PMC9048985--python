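"""Spoiled gradient-echo (SPGR/FLASH) signal physics.

This module holds the steady-state signal equation and its two standard
inversions:

* variable-flip-angle (VFA) T1 mapping — the multi-angle SPGR signal is
  linearized per voxel as Y = Sp * X + const with X = SI/tan(alpha) and
  Y = SI/sin(alpha); the ordinary-least-squares slope Sp gives the
  pre-contrast relaxation time T10 = -Tr / ln(Sp);
* dynamic signal <-> gadolinium concentration conversion — contrast agent
  shortens T1 according to the fast-exchange relation
  1/T1(t) = 1/T10 + r1 * Ct(t), so inverting the SPGR equation for T1(t)
  frame by frame yields the tissue concentration curve Ct(t) in mM.

Invalid voxels and frames (non-physical slope, non-invertible signal
ratio) are flagged with NaN sentinels plus boolean quality masks; nothing
is clamped silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionParams",
    "VFASeries",
    "T1Map",
    "DynamicSeries",
    "ConcentrationSeries",
    "spgr_signal",
    "fit_t10_vfa",
    "signal_to_concentration",
    "concentration_to_signal",
]


@dataclass
class AcquisitionParams:
    """Acquisition constants of the dynamic and VFA scans.

    Parameters
    ----------
    tr : float
        Repetition time of the dynamic (FLASH) scan, seconds.
    flip_angle : float
        Flip angle of the dynamic scan, degrees.
    vfa_angles : tuple of float
        Flip angles of the T1-mapping series, degrees.
    vfa_tr : float
        Repetition time of the VFA scan, seconds.
    r1 : float
        Longitudinal relaxivity of the contrast agent, 1/(s*mM).
        Default 3.11 for gadopentetate at 7 T.
    dt : float
        Dynamic temporal spacing, seconds per frame.
    baseline_frames : int
        Number of pre-contrast dynamics averaged for the baseline S0.
    """

    tr: float = 0.043
    flip_angle: float = 30.0
    vfa_angles: tuple = (5.0, 10.0, 20.0, 35.0)
    vfa_tr: float = 0.100
    r1: float = 3.11
    dt: float = 10.4
    baseline_frames: int = 5

    def __post_init__(self):
        if self.tr <= 0 or self.vfa_tr <= 0:
            raise ValueError("repetition times must be positive")
        if not (0.0 < self.flip_angle <= 90.0):
            raise ValueError("flip_angle must be in (0, 90] degrees")
        self.vfa_angles = tuple(float(a) for a in self.vfa_angles)
        if any(not (0.0 < a <= 90.0) for a in self.vfa_angles):
            raise ValueError("vfa_angles must be in (0, 90] degrees")
        if self.r1 <= 0:
            raise ValueError("r1 must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")


@dataclass
class VFASeries:
    """Multi-flip-angle signal stack: ``signals[..., i]`` at ``angles[i]`` degrees."""

    signals: np.ndarray
    angles: tuple
    mask: np.ndarray

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.angles = tuple(float(a) for a in self.angles)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.angles) < 2:
            raise ValueError("VFA series needs at least 2 flip angles")
        if self.signals.shape[-1] != len(self.angles):
            raise ValueError("last signals axis must index flip angles")
        if self.signals.shape[:-1] != self.mask.shape:
            raise ValueError("signals and mask grids differ")


@dataclass
class T1Map:
    """Per-voxel pre-contrast T1 (seconds) with the fitted VFA slope Sp."""

    t10: np.ndarray
    slope: np.ndarray
    mask: np.ndarray
    valid: np.ndarray


@dataclass
class DynamicSeries:
    """4-D dynamic signal stack ordered (row, col, frame[, slice]).

    ``s0`` is the per-voxel baseline intensity (mean of the first
    ``baseline_frames`` dynamics); ``arrival_index`` is the frame at which
    the contrast bolus reaches the tissue.
    """

    signal: np.ndarray
    time: np.ndarray
    mask: np.ndarray
    s0: np.ndarray | None = None
    arrival_index: int = 0

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.n_frames
        if self.time.shape != (n,):
            raise ValueError("time axis length must match frame axis")
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("time must be strictly increasing and uniform")
        if not (0 <= self.arrival_index < n):
            raise ValueError("arrival_index out of range")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[2]

    def compute_s0(self, baseline_frames: int) -> np.ndarray:
        """Mean of the first ``baseline_frames`` dynamics, per voxel."""
        nb = min(baseline_frames, self.n_frames)
        return self.signal[:, :, :nb, ...].mean(axis=2)


@dataclass
class ConcentrationSeries:
    """Voxelwise tissue concentration Ct(t) in mM, same layout as the dynamics."""

    ct: np.ndarray
    time: np.ndarray
    mask: np.ndarray
    valid: np.ndarray | None = None
    arrival_index: int = 0


def _deg2rad(a):
    return np.deg2rad(np.asarray(a, dtype=float))


def spgr_fraction(t1, tr: float, flip_angle: float):
    """SPGR signal per unit equilibrium magnetization.

    ``(1 - E) sin(theta) / (1 - E cos(theta))`` with ``E = exp(-Tr/T1)``.
    """
    t1 = np.asarray(t1, dtype=float)
    theta = _deg2rad(flip_angle)
    e1 = np.exp(-tr / t1)
    return (1.0 - e1) * np.sin(theta) / (1.0 - e1 * np.cos(theta))


def spgr_signal(t1, s0, params: AcquisitionParams, *, tr: float | None = None,
                flip_angle: float | None = None):
    """Steady-state SPGR signal ``S = S0 (1-E) sin(theta) / (1 - E cos(theta))``.

    Parameters
    ----------
    t1 : array_like
        Longitudinal relaxation time, seconds; must be strictly positive.
    s0 : array_like
        Equilibrium signal scale (a.u.).
    params : AcquisitionParams
        Provides Tr and flip angle of the dynamic scan unless overridden.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be strictly positive")
    tr = params.tr if tr is None else tr
    theta = params.flip_angle if flip_angle is None else flip_angle
    return np.asarray(s0, dtype=float) * spgr_fraction(t1, tr, theta)


def fit_t10_vfa(vfa: VFASeries, params: AcquisitionParams) -> T1Map:
    """Variable-flip-angle T10 mapping by per-voxel linearized OLS.

    For each masked voxel the coordinates X_i = SI_i / tan(alpha_i) and
    Y_i = SI_i / sin(alpha_i) are fitted with an ordinary least-squares
    line; its slope Sp = exp(-Tr/T10) gives T10 = -Tr / ln(Sp).  Voxels
    whose slope falls outside (0, 1), or with degenerate (e.g. all-zero)
    signals, are flagged invalid with NaN — never clamped.
    """
    angles = np.asarray(vfa.angles, dtype=float)
    si = vfa.signals
    x = si / np.tan(_deg2rad(angles))
    y = si / np.sin(_deg2rad(angles))

    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=-1)
    sxy = ((x - xm) * (y - ym)).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx

    valid = vfa.mask & np.isfinite(slope) & (slope > 0.0) & (slope < 1.0) & (sxx > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t10 = np.where(valid, -params.vfa_tr / np.log(np.where(valid, slope, 0.5)), np.nan)
    slope = np.where(vfa.mask, slope, np.nan)
    return T1Map(t10=t10, slope=slope, mask=vfa.mask.copy(), valid=valid)


def _invert_spgr(signal, m0, tr: float, flip_angle: float):
    """Solve the SPGR equation for T1 given the signal and magnetization scale.

    Returns (t1, valid): frames whose signal ratio leaves ``E = exp(-Tr/T1)``
    outside (0, 1) are non-invertible and flagged.
    """
    theta = _deg2rad(flip_angle)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = signal / (m0 * np.sin(theta))
        e1 = (1.0 - y) / (1.0 - y * np.cos(theta))
    valid = np.isfinite(e1) & (e1 > 0.0) & (e1 < 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(valid, -tr / np.log(np.where(valid, e1, 0.5)), np.nan)
    return t1, valid


def signal_to_concentration(dyn: DynamicSeries, t1map: T1Map,
                            params: AcquisitionParams) -> ConcentrationSeries:
    """Convert a dynamic SPGR series into tissue concentration Ct(t), mM.

    The equilibrium magnetization M0 is back-computed per voxel from the
    baseline signal S0 and the pre-contrast T10; each frame's signal is
    then inverted for T1(t) and ``Ct = (1/T1(t) - 1/T10) / r1``.
    Voxels with non-positive baseline and frames with a non-invertible
    signal ratio carry NaN and are flagged in ``valid``.
    """
    if dyn.signal.shape[:2] != t1map.t10.shape[:2]:
        raise ValueError("dynamic series and T1 map grids differ")
    s0 = dyn.s0 if dyn.s0 is not None else dyn.compute_s0(params.baseline_frames)

    t10 = t1map.t10[:, :, np.newaxis, ...] if dyn.signal.ndim == 4 else t1map.t10
    base_valid = t1map.valid & (s0 > 0)
    frac0 = spgr_fraction(np.where(t1map.valid, t1map.t10, 1.0), params.tr, params.flip_angle)
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s0 / frac0

    if dyn.signal.ndim == 4:  # (row, col, frame, slice)
        m0b = m0[:, :, np.newaxis, :]
        t10b = t1map.t10[:, :, np.newaxis, :]
        vb = base_valid[:, :, np.newaxis, :]
    else:
        m0b = m0[..., np.newaxis] if dyn.signal.ndim == 3 else m0
        t10b = t1map.t10[..., np.newaxis] if dyn.signal.ndim == 3 else t1map.t10
        vb = base_valid[..., np.newaxis] if dyn.signal.ndim == 3 else base_valid

    t1_t, inv_valid = _invert_spgr(dyn.signal, m0b, params.tr, params.flip_angle)
    valid = vb & inv_valid
    with np.errstate(divide="ignore", invalid="ignore"):
        ct = (1.0 / t1_t - 1.0 / t10b) / params.r1
    ct = np.where(valid, ct, np.nan)
    return ConcentrationSeries(ct=ct, time=dyn.time.copy(), mask=dyn.mask.copy(),
                               valid=valid, arrival_index=dyn.arrival_index)


def concentration_to_signal(ct: ConcentrationSeries, t1map: T1Map,
                            params: AcquisitionParams, m0=1.0) -> DynamicSeries:
    """Forward-simulate the dynamic SPGR signal from a concentration series.

    ``1/T1(t) = 1/T10 + r1 * Ct(t)`` then the SPGR equation; exact inverse
    of :func:`signal_to_concentration` in exact arithmetic.  ``m0`` is the
    per-voxel (or scalar) equilibrium magnetization scale.
    """
    cta = np.asarray(ct.ct, dtype=float)
    t10 = t1map.t10
    if cta.ndim == 4:
        t10b = t10[:, :, np.newaxis, :]
    elif cta.ndim == 3:
        t10b = t10[..., np.newaxis] if t10.ndim == cta.ndim - 1 else t10
    else:
        t10b = t10
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_t = 1.0 / t10b + params.r1 * cta
    if np.any(r1_t[np.isfinite(r1_t)] <= 0):
        raise ValueError("concentration drives 1/T1 non-positive")
    t1_t = 1.0 / r1_t
    m0a = np.asarray(m0, dtype=float)
    if m0a.ndim and cta.ndim == 4 and m0a.ndim == 3:
        m0a = m0a[:, :, np.newaxis, :]
    elif m0a.ndim and cta.ndim == 3 and m0a.ndim == 2:
        m0a = m0a[..., np.newaxis]
    signal = m0a * spgr_fraction(t1_t, params.tr, params.flip_angle)
    nb = min(params.baseline_frames, signal.shape[2]) if signal.ndim >= 3 else 1
    s0 = signal[:, :, :nb, ...].mean(axis=2) if signal.ndim >= 3 else None
    return DynamicSeries(signal=signal, time=ct.time.copy(), mask=ct.mask.copy(),
                         s0=s0, arrival_index=ct.arrival_index)
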