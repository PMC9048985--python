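"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's closed-form code paths:
formulas are evaluated with the ``math`` module, convolutions by
trapezoidal quadrature on an oversampled grid, model fits by grid search
plus Nelder-Mead on the quadrature forward model, and morphology by an
explicit neighbor scan.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize


def spgr_signal_oracle(t1, s0, tr, flip_deg):
    """Direct evaluation of the steady-state SPGR signal equation."""
    th = math.radians(flip_deg)
    e1 = math.exp(-tr / t1)
    return s0 * (1 - e1) * math.sin(th) / (1 - e1 * math.cos(th))


def concentration_to_signal_oracle(ct_mm, t10, r1, tr, flip_deg, m0=1.0):
    """Contrast-shortened T1, then the SPGR equation."""
    r1_total = 1.0 / t10 + r1 * ct_mm
    return spgr_signal_oracle(1.0 / r1_total, m0, tr, flip_deg)


def biexp_aif_oracle(a, b, c1, c2, t0_s, t_s):
    """Plain evaluation of the bi-exponential plasma curve (rates min^-1)."""
    u = (t_s - t0_s) / 60.0
    if u < 0:
        return 0.0
    return a * math.exp(-c1 * u) + b * math.exp(-c2 * u)


def convolution_oracle(aifp, kep, times_s, oversample=100):
    """Trapezoidal quadrature of integral Cp(tau) exp(-kep (t-tau)) dtau.

    ``aifp`` is an AIFParams-like object; result in mM*min, matching the
    closed-form kernel.  Oversampling is relative to the output grid.
    """
    times_s = np.asarray(times_s, dtype=float)
    out = np.zeros_like(times_s)
    for j, t in enumerate(times_s):
        if t <= aifp.t0:
            continue
        n = max(int(oversample * (j + 1)), 50)
        tau = np.linspace(aifp.t0, t, n)
        u = (tau - aifp.t0) / 60.0
        cp = aifp.a * np.exp(-aifp.c1 * u) + aifp.b * np.exp(-aifp.c2 * u)
        kernel = np.exp(-kep * (t - tau) / 60.0)
        out[j] = np.trapezoid(cp * kernel, tau) / 60.0
    return out


def tofts_forward_oracle(ktrans, kep, vp, aifp, times_s, oversample=100):
    """Quadrature-based extended-Tofts forward model (vp=0 gives Tofts)."""
    conv = convolution_oracle(aifp, kep, times_s, oversample=oversample)
    times_s = np.asarray(times_s, dtype=float)
    u = np.maximum(times_s - aifp.t0, 0.0) / 60.0
    cp = np.where(times_s >= aifp.t0,
                  aifp.a * np.exp(-aifp.c1 * u) + aifp.b * np.exp(-aifp.c2 * u),
                  0.0)
    return vp * cp + ktrans * conv


def fit_voxel_oracle(ct, aifp, times_s, model="extofts", oversample=25):
    """Independent NLLS fit: coarse grid search then Nelder-Mead, with the
    quadrature forward model.  Returns (ktrans, kep[, vp])."""
    ct = np.asarray(ct, dtype=float)

    def cost(theta):
        if model == "tofts":
            kt, kep = theta
            vp = 0.0
        else:
            kt, kep, vp = theta
        if kt < 0 or kep <= 1e-4 or vp < 0 or vp > 1:
            return 1e12
        pred = tofts_forward_oracle(kt, kep, vp, aifp, times_s,
                                    oversample=oversample)
        return float(((pred - ct) ** 2).sum())

    grid_kt = (0.02, 0.1, 0.3)
    grid_kep = (0.2, 0.5, 1.5)
    grid_vp = (0.0, 0.03) if model == "extofts" else (None,)
    best, best_c = None, np.inf
    for kt in grid_kt:
        for kep in grid_kep:
            for vp in grid_vp:
                theta = (kt, kep) if model == "tofts" else (kt, kep, vp)
                c = cost(theta)
                if c < best_c:
                    best, best_c = theta, c
    res = minimize(cost, best, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000})
    return res.x


def rim_pixels_oracle(mask2d):
    """Boundary tracing by neighbor scan: lesion pixels with any of their 8
    neighbors (or the image border) outside the lesion."""
    m = np.asarray(mask2d, dtype=bool)
    h, w = m.shape
    rim = np.zeros_like(m)
    for i in range(h):
        for j in range(w):
            if not m[i, j]:
                continue
            boundary = False
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if ni < 0 or nj < 0 or ni >= h or nj >= w or not m[ni, nj]:
                        boundary = True
            rim[i, j] = boundary
    return rim


def agreement_oracle(pred, target, mask):
    """Spreadsheet-style per-pixel agreement statistics via explicit loops."""
    ps, ts = [], []
    flat_p = np.asarray(pred, dtype=float).ravel()
    flat_t = np.asarray(target, dtype=float).ravel()
    flat_m = np.asarray(mask, dtype=bool).ravel()
    for p, t, m in zip(flat_p, flat_t, flat_m):
        if m:
            ps.append(p)
            ts.append(t)
    n = len(ps)
    sq = sum((p - t) ** 2 for p, t in zip(ps, ts))
    rmse = math.sqrt(sq / n)
    tmean = sum(ts) / n
    tsd = math.sqrt(sum((t - tmean) ** 2 for t in ts) / (n - 1))
    diffs = [p - t for p, t in zip(ps, ts)]
    bias = sum(diffs) / n
    dsd = math.sqrt(sum((d - bias) ** 2 for d in diffs) / (n - 1))
    # OLS slope/intercept of pred on target
    pmean = sum(ps) / n
    sxx = sum((t - tmean) ** 2 for t in ts)
    sxy = sum((t - tmean) * (p - pmean) for t, p in zip(ts, ps))
    slope = sxy / sxx
    intercept = pmean - slope * tmean
    return {"rmse": rmse, "nrmse": rmse / tsd, "bias": bias,
            "loa_low": bias - 1.96 * dsd, "loa_high": bias + 1.96 * dsd,
            "slope": slope, "intercept": intercept, "n_pixels": n}
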