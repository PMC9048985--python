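"""Agreement statistics between predicted and target PK maps.

Pooled masked pixels are compared by root mean squared error, normalized
RMSE (RMSE divided by the sample standard deviation of the target — so
nRMSE < 1 means the prediction beats a constant mean predictor), ordinary
least-squares regression of prediction on target, and Bland-Altman bias
with 95% limits of agreement.  ROI helpers derive the whole-lesion and
peripheral-rim masks (the one-pixel-wide ring just inside the lesion
boundary) used for intratumoral and peripheral analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_erosion

__all__ = ["AgreementReport", "agreement", "lesion_masks", "fold_table",
           "bland_altman_plot", "scatter_plot"]


@dataclass
class AgreementReport:
    """Summary of pixelwise agreement between a prediction and its target."""

    rmse: float
    nrmse: float
    slope: float
    intercept: float
    r: float
    p: float
    bias: float
    loa_low: float
    loa_high: float
    n_pixels: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def agreement(pred: np.ndarray, target: np.ndarray,
              mask: np.ndarray) -> AgreementReport:
    """Pixelwise agreement statistics over the masked region.

    RMSE = sqrt(mean((pred - target)^2)); nRMSE = RMSE / SD(target) with
    the sample (n-1) standard deviation, NaN when the target is constant;
    regression is prediction on target (target on the x-axis); limits of
    agreement are bias +/- 1.96 SD of the differences.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    p = np.asarray(pred, dtype=float)[mask]
    t = np.asarray(target, dtype=float)[mask]
    diff = p - t
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    sd_t = float(t.std(ddof=1)) if t.size > 1 else 0.0
    nrmse = rmse / sd_t if sd_t > 0 else np.nan
    if t.size > 1 and sd_t > 0:
        reg = stats.linregress(t, p)
        slope, intercept, r, pval = reg.slope, reg.intercept, reg.rvalue, reg.pvalue
    else:
        slope, intercept, r, pval = np.nan, np.nan, np.nan, np.nan
    bias = float(diff.mean())
    sd_d = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return AgreementReport(rmse=rmse, nrmse=nrmse, slope=float(slope),
                           intercept=float(intercept), r=float(r), p=float(pval),
                           bias=bias, loa_low=bias - 1.96 * sd_d,
                           loa_high=bias + 1.96 * sd_d, n_pixels=int(t.size))


def lesion_masks(lesion_mask: np.ndarray):
    """Whole-lesion and peripheral-rim masks.

    The rim is the lesion minus its one-voxel erosion (8-connectivity),
    computed slice by slice in 2-D: the single-pixel ring just inside the
    lesion boundary.  Returns ``(whole, rim)``.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    structure = np.ones((3, 3), dtype=bool)

    def rim2d(m):
        return m & ~binary_erosion(m, structure=structure)

    if lesion_mask.ndim == 2:
        rim = rim2d(lesion_mask)
    elif lesion_mask.ndim == 3:
        rim = np.stack([rim2d(lesion_mask[:, :, s])
                        for s in range(lesion_mask.shape[2])], axis=2)
    else:
        raise ValueError("lesion mask must be 2-D or 3-D")
    return lesion_mask.copy(), rim


def fold_table(reports: dict) -> pd.DataFrame:
    """Cross-validation summary: parameters x folds table of RMSE and nRMSE.

    ``reports`` maps a parameter name to its list of per-fold
    :class:`AgreementReport` objects; all parameters must have the same
    fold count.
    """
    if not reports:
        raise ValueError("no reports given")
    rows = []
    for param, fold_reports in reports.items():
        for metric in ("rmse", "nrmse"):
            row = {"parameter": param, "metric": metric}
            for k, rep in enumerate(fold_reports):
                row[f"fold_{k + 1}"] = getattr(rep, metric)
            rows.append(row)
    return pd.DataFrame(rows)


def _pyplot():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def bland_altman_plot(pred, target, mask, path: str, title: str = ""):
    """Difference-vs-mean plot with bias and 95% limits of agreement."""
    plt = _pyplot()
    rep = agreement(pred, target, mask)
    p = np.asarray(pred, dtype=float)[np.asarray(mask, bool)]
    t = np.asarray(target, dtype=float)[np.asarray(mask, bool)]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((p + t) / 2, p - t, s=4, alpha=0.4)
    for y, ls in ((rep.bias, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=ls, linewidth=1)
    ax.set_xlabel("mean of prediction and target")
    ax.set_ylabel("prediction - target")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return rep


def scatter_plot(pred, target, mask, path: str, title: str = ""):
    """Prediction-vs-target scatter with the fitted regression line."""
    plt = _pyplot()
    rep = agreement(pred, target, mask)
    p = np.asarray(pred, dtype=float)[np.asarray(mask, bool)]
    t = np.asarray(target, dtype=float)[np.asarray(mask, bool)]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(t, p, s=4, alpha=0.4)
    xs = np.linspace(t.min(), t.max(), 50)
    ax.plot(xs, rep.slope * xs + rep.intercept, "k-", linewidth=1)
    ax.set_xlabel("target")
    ax.set_ylabel("prediction")
    ax.set_title(title or f"r={rep.r:.3f}, nRMSE={rep.nrmse:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return rep
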