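"""Tofts and extended-Tofts tracer-kinetic models: forward and inverse.

Forward models (time in seconds, rates in min^-1, concentrations in mM):

    Tofts:     Ct(t) = Ktrans * integral_0^t Cp(tau) exp(-Kep (t - tau)) dtau
    Ex-Tofts:  Ct(t) = Vp * Cp(t) + Tofts term

With the bi-exponential population AIF the convolution has a closed form
(see :mod:`dcepk.aif`), so model evaluation and its Jacobian are analytic.
The inverse problem is bounded nonlinear least squares per voxel over
(Ktrans, Kep[, Vp]); Ve is derived afterwards as Ktrans / Kep, the
fractional extravascular extracellular volume.

Fitting is deterministic: fixed initialization (optionally a small
multistart grid), trust-region-reflective steps, analytic Jacobian, and a
per-voxel contract that is independent of the voxel visiting order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .aif import AIFParams, aif_integral, evaluate_aif

__all__ = [
    "TissueParams",
    "PKMaps",
    "FitOptions",
    "tofts_forward",
    "extofts_forward",
    "fit_voxel",
    "fit_maps",
]


@dataclass
class TissueParams:
    """Voxel kinetic parameters: ktrans, kep in min^-1; vp, ve fractions."""

    ktrans: float
    kep: float
    vp: float = 0.0

    def __post_init__(self):
        if self.ktrans < 0:
            raise ValueError("ktrans must be nonnegative")
        if self.ktrans > 0 and self.kep <= 0:
            raise ValueError("kep must be positive when ktrans > 0")
        if not (0.0 <= self.vp <= 1.0):
            raise ValueError("vp must be a fraction in [0, 1]")

    @property
    def ve(self) -> float:
        return self.ktrans / self.kep if self.kep > 0 else np.nan


@dataclass
class PKMaps:
    """Per-voxel kinetic parameter maps plus fit diagnostics."""

    ktrans: np.ndarray
    kep: np.ndarray
    ve: np.ndarray
    model_tag: str
    mask: np.ndarray
    vp: np.ndarray | None = None
    fit_rss: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self):
        if self.model_tag not in ("tofts", "extofts"):
            raise ValueError("model_tag must be 'tofts' or 'extofts'")
        if (self.vp is not None) != (self.model_tag == "extofts"):
            raise ValueError("vp map present iff extended-Tofts")

    @property
    def convergence_fraction(self) -> float:
        if self.converged is None:
            return np.nan
        m = self.mask
        return float(self.converged[m].mean()) if m.any() else np.nan

    def parameter_names(self) -> tuple:
        return ("ktrans", "kep", "ve") + (("vp",) if self.vp is not None else ())


@dataclass
class FitOptions:
    """Deterministic fit configuration for the voxelwise NLLS inversion.

    Bounds and the fixed starting point make fits reproducible; the
    optional multistart grid (coarse log-spaced ktrans/kep, linear vp)
    guards against local minima at high noise.
    """

    ktrans_bounds: tuple = (0.0, 5.0)
    kep_bounds: tuple = (1e-3, 10.0)
    vp_bounds: tuple = (0.0, 1.0)
    x0: tuple = (0.05, 0.5, 0.02)
    multistart: bool = False
    multistart_grid: tuple = ((0.01, 0.1, 0.5), (0.1, 0.5, 2.0), (0.0, 0.02, 0.08))
    ftol: float = 1e-10
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 200
    init: str = "fixed"  # or "llsq": Murase linear-least-squares warm start


def tofts_forward(p: TissueParams, aif: AIFParams, time_s) -> np.ndarray:
    """Classical Tofts tissue curve Ct(t) in mM (closed form)."""
    time_s = np.asarray(time_s, dtype=float)
    if p.ktrans == 0.0:
        return np.zeros_like(time_s)
    return p.ktrans * aif_integral(aif, p.kep, time_s)


def extofts_forward(p: TissueParams, aif: AIFParams, time_s) -> np.ndarray:
    """Extended-Tofts tissue curve: adds the intravascular term Vp*Cp(t)."""
    return p.vp * evaluate_aif(aif, time_s) + tofts_forward(p, aif, time_s)


def extofts_forward_map(ktrans, kep, vp, aif: AIFParams, time_s) -> np.ndarray:
    """Vectorized extended-Tofts forward over arrays of voxel parameters.

    ``ktrans, kep, vp`` have shape (n_vox,); returns (n_vox, n_frames).
    Used by the phantom simulator; agrees with :func:`extofts_forward`
    voxel by voxel.
    """
    time_s = np.asarray(time_s, dtype=float)
    ktrans = np.asarray(ktrans, dtype=float)[:, np.newaxis]
    kep = np.asarray(kep, dtype=float)[:, np.newaxis]
    vp = np.asarray(vp, dtype=float)[:, np.newaxis]
    cp = evaluate_aif(aif, time_s)[np.newaxis, :]
    conv = aif_integral(aif, np.maximum(kep, 1e-12), time_s[np.newaxis, :])
    return vp * cp + np.where(ktrans > 0, ktrans * conv, 0.0)


class _VoxelModel:
    """Cached forward model + Jacobian for one voxel's time grid.

    The AIF exponentials depend only on the fixed time samples, so they
    are precomputed once; each optimizer iteration then needs a single
    ``exp(-kep u)`` evaluation.  The (ct, jac) pair for the last theta is
    memoized because scipy calls the residual and Jacobian separately.
    """

    def __init__(self, aif: AIFParams, time_s, model: str):
        self.model = model
        self.u = np.maximum((np.asarray(time_s, dtype=float) - aif.t0) / 60.0, 0.0)
        self.post = (np.asarray(time_s, dtype=float) - aif.t0) >= 0.0
        self.amps = (aif.a, aif.b)
        self.cs = (aif.c1, aif.c2)
        self.ecs = [np.exp(-c * self.u) for c in self.cs]
        self.cp = np.where(self.post, aif.a * self.ecs[0] + aif.b * self.ecs[1], 0.0)
        self._theta = None

    def __call__(self, theta):
        key = tuple(theta)
        if self._theta == key:
            return self._cached
        if self.model == "tofts":
            ktrans, kep = theta
            vp = 0.0
        else:
            ktrans, kep, vp = theta
        u = self.u
        ek = np.exp(-kep * u)
        conv = np.zeros_like(u)
        dconv = np.zeros_like(u)
        for amp, c, ec in zip(self.amps, self.cs, self.ecs):
            d = kep - c
            if abs(d) < 1e-8:
                g = u * ec * (1.0 - d * u / 2.0)
                dg = -0.5 * u ** 2 * ec * (1.0 - d * u * 2.0 / 3.0)
            else:
                g = (ec - ek) / d
                dg = (u * ek - g) / d
            conv += amp * g
            dconv += amp * dg
        conv = np.where(self.post, conv, 0.0)
        dconv = np.where(self.post, dconv, 0.0)
        ct = ktrans * conv
        cols = [conv, ktrans * dconv]
        if self.model == "extofts":
            ct = ct + vp * self.cp
            cols.append(self.cp)
        self._theta = key
        self._cached = (ct, np.column_stack(cols))
        return self._cached


def _llsq_start(vm: _VoxelModel, yy, tt_s, model: str):
    """Murase linear-least-squares warm start.

    Integrating the tissue ODE gives the linear relation
    ``Ct = vp Cp + (Ktrans + Kep vp) int Cp - Kep int Ct``, solvable by
    OLS with trapezoidal cumulative integrals of the measured data.
    """
    from scipy.integrate import cumulative_trapezoid
    u = (np.asarray(tt_s, dtype=float) - tt_s[0]) / 60.0
    icp = cumulative_trapezoid(vm.cp, u, initial=0.0)
    ict = cumulative_trapezoid(yy, u, initial=0.0)
    if model == "tofts":
        A = np.column_stack([icp, -ict])
        coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
        return float(coef[0]), float(coef[1])
    A = np.column_stack([vm.cp, icp, -ict])
    coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
    vp, b1, kep = float(coef[0]), float(coef[1]), float(coef[2])
    return b1 - kep * vp, kep, vp


def fit_voxel(ct, aif: AIFParams, time_s, model: str = "tofts",
              opts: FitOptions | None = None, arrival_index: int = 0,
              _vm_cache: dict | None = None):
    """Fit one voxel's concentration curve by bounded nonlinear least squares.

    Pre-arrival frames (before ``arrival_index``) and non-finite frames are
    excluded from the residual.  Returns ``(TissueParams, diagnostics)``
    where diagnostics carries the residual sum of squares, convergence
    flag, and whether any parameter sits on a bound.
    """
    opts = opts or FitOptions()
    if model not in ("tofts", "extofts"):
        raise ValueError("model must be 'tofts' or 'extofts'")
    ct = np.asarray(ct, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    keep = np.isfinite(ct)
    keep[:arrival_index] = False
    tt, yy = time_s[keep], ct[keep]
    diagnostics = {"rss": np.nan, "converged": False, "at_bounds": False,
                   "n_frames": int(keep.sum())}
    if keep.sum() < 8:
        return None, diagnostics

    if _vm_cache is not None:
        vm = _vm_cache.setdefault(keep.tobytes(), _VoxelModel(aif, tt, model))
    else:
        vm = _VoxelModel(aif, tt, model)

    if model == "tofts":
        lo = (opts.ktrans_bounds[0], opts.kep_bounds[0])
        hi = (opts.ktrans_bounds[1], opts.kep_bounds[1])
        starts = [opts.x0[:2]]
        if opts.multistart:
            starts = [(k, e) for k in opts.multistart_grid[0]
                      for e in opts.multistart_grid[1]]
    else:
        lo = (opts.ktrans_bounds[0], opts.kep_bounds[0], opts.vp_bounds[0])
        hi = (opts.ktrans_bounds[1], opts.kep_bounds[1], opts.vp_bounds[1])
        starts = [opts.x0]
        if opts.multistart:
            starts = [(k, e, v) for k in opts.multistart_grid[0]
                      for e in opts.multistart_grid[1]
                      for v in opts.multistart_grid[2]]
    if opts.init == "llsq":
        starts = [_llsq_start(vm, yy, tt, model)]

    def residual(theta):
        return vm(theta)[0] - yy

    def jac(theta):
        return vm(theta)[1]

    best = None
    for x0 in starts:
        x0c = np.clip(x0, np.asarray(lo) + 1e-12, hi)
        sol = least_squares(residual, x0c, jac=jac, bounds=(lo, hi),
                            ftol=opts.ftol, xtol=opts.xtol, gtol=opts.gtol,
                            max_nfev=opts.max_nfev, method="trf")
        if best is None or sol.cost < best.cost:
            best = sol

    theta = best.x
    p = TissueParams(ktrans=float(theta[0]), kep=float(theta[1]),
                     vp=float(theta[2]) if model == "extofts" else 0.0)
    eps = 1e-9
    at_bounds = bool(np.any(np.abs(theta - np.asarray(lo)) < eps)
                     or np.any(np.abs(theta - np.asarray(hi)) < eps))
    diagnostics.update(rss=float(2.0 * best.cost), converged=bool(best.success),
                       at_bounds=at_bounds)
    return p, diagnostics


def fit_maps(conc, aif: AIFParams, model: str = "tofts",
             opts: FitOptions | None = None) -> PKMaps:
    """Voxelwise NLLS inversion over all masked voxels of a concentration series.

    Each voxel is fitted independently with the same deterministic options,
    so the result does not depend on the visiting order.  Voxels that fail
    (too few usable frames) carry NaN and ``converged=False``.
    """
    opts = opts or FitOptions()
    mask = np.asarray(conc.mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    ct = np.asarray(conc.ct, dtype=float)
    shape = mask.shape
    n_par = 3 if model == "extofts" else 2

    maps = {name: np.full(shape, np.nan) for name in ("ktrans", "kep", "vp")}
    rss = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)

    # ct layout: mask shape + frame axis at position 2 (row, col, frame[, slice])
    if ct.ndim == mask.ndim + 1:
        move = np.moveaxis(ct, 2, -1)  # (..., frames) aligned with mask
    else:
        raise ValueError("concentration array must have one frame axis")

    idx = np.argwhere(mask)
    vm_cache: dict = {}
    for vox in idx:
        curve = move[tuple(vox)]
        p, diag = fit_voxel(curve, aif, conc.time, model=model, opts=opts,
                            arrival_index=conc.arrival_index,
                            _vm_cache=vm_cache)
        key = tuple(vox)
        if p is not None:
            maps["ktrans"][key] = p.ktrans
            maps["kep"][key] = p.kep
            maps["vp"][key] = p.vp
        rss[key] = diag["rss"]
        converged[key] = diag["converged"]

    with np.errstate(divide="ignore", invalid="ignore"):
        ve = maps["ktrans"] / maps["kep"]
    return PKMaps(ktrans=maps["ktrans"], kep=maps["kep"], ve=ve,
                  vp=maps["vp"] if model == "extofts" else None,
                  model_tag=model, mask=mask.copy(), fit_rss=rss,
                  converged=converged)
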