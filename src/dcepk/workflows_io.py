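"""File I/O, configuration, contrast-arrival detection, and pipelines.

Images travel as NIfTI volumes (nibabel), dimension order
(row, col, frame-or-angle, slice) for 4-D stacks and (row, col, slice)
for maps and masks, with a JSON sidecar for acquisition metadata that
NIfTI headers cannot hold (flip angles, TR, frame spacing).  Tables are
CSV.  Every pipeline run writes a manifest (resolved configuration,
package version, seed) sufficient to reproduce it bit-identically.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aif import AIFParams
from .cnn_surrogate import (NetworkSpec, TrainSpec, make_fold_plan,
                            preprocess_for_net, run_kfold, save_model)
from .evaluation import fold_table
from .phantom import (LesionSpec, PhantomSpec, make_cohort,
                      signal_sigma_for_concentration, simulate_study)
from .pk_models import FitOptions, fit_maps
from .signal_model import (AcquisitionParams, DynamicSeries, VFASeries,
                           fit_t10_vfa, signal_to_concentration)

__all__ = ["read_nifti", "write_nifti", "load_config", "detect_arrival",
           "run_pk_pipeline", "run_cnn_pipeline", "write_phantom_study",
           "load_study", "build_params"]

log = logging.getLogger("dcepk")


# --------------------------------------------------------------------- I/O

def write_nifti(path, data, affine=None):
    """Write an array as NIfTI; boolean arrays are stored as uint8 0/1."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine if affine is not None else np.eye(4)),
             str(path))


def read_nifti(path):
    """Read a NIfTI volume; returns ``(array, affine)``."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def _write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def load_config(path) -> dict:
    """Load a YAML study configuration; referenced files must exist."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for key in ("dynamic", "vfa", "mask", "lesion_mask"):
        p = cfg.get("paths", {}).get(key)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured {key} path does not exist: {p}")
    return cfg


def build_params(cfg: dict):
    """Materialize typed parameter objects from a config dictionary."""
    acq = AcquisitionParams(**cfg.get("acquisition", {}))
    aif = AIFParams(**cfg.get("aif", {}))
    ph = dict(cfg.get("phantom", {}))
    if "lesions" in ph:
        ph["lesions"] = tuple(LesionSpec(**{**l, "center": tuple(l["center"]),
                                            "radii": tuple(l["radii"])})
                              for l in ph["lesions"])
    if "shape" in ph:
        ph["shape"] = tuple(ph["shape"])
    phantom = PhantomSpec(**ph)
    net_cfg = dict(cfg.get("network", {}))
    profile = net_cfg.pop("profile", "full")
    if profile == "reduced":
        nspec = NetworkSpec.reduced()
        nspec = replace(nspec, **{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in net_cfg.items()})
    else:
        nspec = NetworkSpec(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in net_cfg.items()})
    tspec = TrainSpec(**cfg.get("train", {}))
    fit_opts = FitOptions(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in cfg.get("fit", {}).items()})
    return acq, aif, phantom, nspec, tspec, fit_opts


def _manifest(outdir: Path, cfg: dict, seed):
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(outdir / "manifest.json",
                {"config": cfg, "version": __version__, "seed": seed})
    with open(outdir / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)


# ------------------------------------------------------- arrival detection

def detect_arrival(dyn: DynamicSeries, k: float = 5.0, sustain: int = 2,
                   default: int | None = None) -> int:
    """First frame whose masked-mean signal exceeds the running-baseline
    mean by ``k`` baseline SDs, sustained for ``sustain`` frames.

    Falls back to ``default`` (or the series' recorded arrival_index) with
    a warning when no enhancement is detectable, e.g. on a flat series.
    """
    n = dyn.n_frames
    if n < 10:
        raise ValueError("arrival detection needs at least 10 frames")
    if dyn.signal.ndim == 4:
        curve = np.array([dyn.signal[:, :, t, :][dyn.mask].mean() for t in range(n)])
    else:
        curve = np.array([dyn.signal[:, :, t][dyn.mask].mean() for t in range(n)])
    for i in range(3, n - sustain + 1):
        base = curve[:i]
        thr = base.mean() + k * base.std()
        if np.all(curve[i:i + sustain] > thr):
            return i
    fallback = default if default is not None else dyn.arrival_index
    log.warning("no contrast arrival detected; using fallback frame %d", fallback)
    return int(fallback)


# --------------------------------------------------------------- pipelines

def write_phantom_study(study, outdir, acq: AcquisitionParams):
    """Write one simulated subject: NIfTI volumes, truth CSV, spec echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_nifti(outdir / "dynamic.nii", study.dynamic.signal)
    write_nifti(outdir / "vfa.nii", study.vfa.signals)
    write_nifti(outdir / "brain_mask.nii", study.brain_mask)
    write_nifti(outdir / "lesion_mask.nii", study.lesion_mask)
    for name in ("ktrans", "kep", "ve", "vp"):
        write_nifti(outdir / f"truth_{name}.nii", getattr(study.truth, name))
    _write_json(outdir / "meta.json", {
        "tr": acq.tr, "flip_angle": acq.flip_angle, "vfa_tr": acq.vfa_tr,
        "vfa_angles": acq.vfa_angles, "dt": study.spec.dt, "r1": acq.r1,
        "arrival_index": study.spec.arrival_index, "m0": study.spec.m0,
    })
    mask = study.brain_mask
    rows = {"voxel": [tuple(int(v) for v in vox) for vox in np.argwhere(mask)]}
    for name in ("ktrans", "kep", "ve", "vp"):
        rows[name] = getattr(study.truth, name)[mask]
    pd.DataFrame(rows).to_csv(outdir / "truth_values.csv", index=False)
    spec_dict = asdict(study.spec)
    spec_dict["lesions"] = [asdict(l) for l in study.spec.lesions]
    with open(outdir / "phantom_spec.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(spec_dict, default=_jsonable)), fh)


def load_study(subject_dir):
    """Load a subject written by :func:`write_phantom_study`."""
    d = Path(subject_dir)
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    signal, _ = read_nifti(d / "dynamic.nii")
    mask, _ = read_nifti(d / "brain_mask.nii")
    mask = mask.astype(bool)
    vfa_sig, _ = read_nifti(d / "vfa.nii")
    time = np.arange(signal.shape[2]) * meta["dt"]
    dyn = DynamicSeries(signal=signal, time=time, mask=mask,
                        arrival_index=int(meta["arrival_index"]))
    vfa = VFASeries(signals=vfa_sig, angles=tuple(meta["vfa_angles"]), mask=mask)
    lesion = None
    if (d / "lesion_mask.nii").exists():
        lesion, _ = read_nifti(d / "lesion_mask.nii")
        lesion = lesion.astype(bool)
    return dyn, vfa, lesion, meta


def pk_pipeline(dyn: DynamicSeries, vfa: VFASeries, acq: AcquisitionParams,
                aif: AIFParams, models=("tofts", "extofts"),
                fit_opts: FitOptions | None = None, arrival: int | None = None):
    """In-memory PK modeling chain: arrival -> VFA T10 -> Ct(t) -> NLLS maps.

    Returns ``(maps_by_model, t1map, conc, arrival_index)``.
    """
    t0 = _time.monotonic()
    if arrival is None:
        arrival = detect_arrival(dyn)
    dyn = replace(dyn, arrival_index=arrival) if dyn.arrival_index != arrival else dyn
    dyn.s0 = dyn.compute_s0(min(acq.baseline_frames, max(arrival, 1)))
    t1map = fit_t10_vfa(vfa, acq)
    conc = signal_to_concentration(dyn, t1map, acq)
    aif_t = replace(aif, t0=arrival * acq.dt) if aif.t0 == 0 else aif
    out = {}
    for model in models:
        out[model] = fit_maps(conc, aif_t, model=model, opts=fit_opts)
        log.info("fitted %s maps: convergence %.3f (%.1f s elapsed)", model,
                 out[model].convergence_fraction, _time.monotonic() - t0)
    return out, t1map, conc, arrival


def _diagnostics_frame(maps):
    mask = maps.mask
    vox = np.argwhere(mask)
    data = {"row": vox[:, 0], "col": vox[:, 1]}
    if vox.shape[1] > 2:
        data["slice"] = vox[:, 2]
    for name in maps.parameter_names():
        data[name] = getattr(maps, name)[mask]
    data["rss"] = maps.fit_rss[mask]
    data["converged"] = maps.converged[mask]
    return pd.DataFrame(data)


def run_pk_pipeline(cfg: dict, outdir) -> dict:
    """Config-driven PK mapping for one subject directory; writes maps,
    diagnostics and a manifest.  Deterministic given the config."""
    outdir = Path(outdir)
    acq, aif, _, _, _, fit_opts = build_params(cfg)
    subject_dir = cfg["paths"]["subject"]
    dyn, vfa, _lesion, _meta = load_study(subject_dir)
    models = tuple(cfg.get("models", ("tofts", "extofts")))
    arrival = cfg.get("arrival_index")
    maps, t1map, conc, arrival = pk_pipeline(dyn, vfa, acq, aif, models=models,
                                             fit_opts=fit_opts, arrival=arrival)
    _manifest(outdir, cfg, cfg.get("seed", 0))
    write_nifti(outdir / "t10.nii", t1map.t10)
    for model, m in maps.items():
        for name in m.parameter_names():
            write_nifti(outdir / f"{model}_{name}.nii", getattr(m, name))
        _diagnostics_frame(m).to_csv(outdir / f"{model}_diagnostics.csv",
                                     index=False)
    _write_json(outdir / "arrival.json", {"arrival_index": arrival})
    return maps


def run_cnn_pipeline(cfg: dict, outdir, subjects_data) -> dict:
    """K-fold CNN training/evaluation over prepared subject arrays.

    ``subjects_data`` is a list of dicts with keys ``signal`` (4-D),
    ``mask``, ``lesion_mask``, ``target`` (the PK map to learn).  Writes
    fold table, loss histories, held-out predictions and checkpoints.
    """
    outdir = Path(outdir)
    _, _, _, nspec, tspec, _ = build_params(cfg)
    seed = int(cfg.get("seed", 0))
    smooth = float(cfg.get("preprocess", {}).get("smooth_sigma", 0.0))

    inputs, targets, masks, lesions = [], [], [], []
    for sd in subjects_data:
        inputs.append(preprocess_for_net(sd["signal"], sd["mask"],
                                         smooth_sigma=smooth))
        targets.append(np.nan_to_num(sd["target"]))
        masks.append(np.asarray(sd["mask"], bool))
        lesions.append(np.asarray(sd["lesion_mask"], bool))

    plan = make_fold_plan(len(subjects_data), masks[0].shape[-1], seed=seed)
    result = run_kfold(inputs, targets, masks, lesions, plan, nspec, tspec,
                       seed=seed)
    _manifest(outdir, cfg, seed)
    reports = {"parameter": [f["report"] for f in result["folds"]]}
    fold_table(reports).to_csv(outdir / "fold_table.csv", index=False)
    for f in result["folds"]:
        k = f["fold"]
        write_nifti(outdir / f"pred_fold{k}.nii", f["prediction"])
        f["model"].history.to_csv(outdir / f"loss_fold{k}.csv", index=False)
        save_model(f["model"], outdir / f"weights_fold{k}.npz")
    _write_json(outdir / "summary.json", {
        "median_nrmse": result["median_nrmse"],
        "nrmse_per_fold": result["nrmse_per_fold"],
        "ensemble": result["ensemble"].to_dict(),
    })
    return result


def export_aif_curve(aif: AIFParams, time_s, path):
    """Write the sampled plasma curve Cp(t) as a two-column CSV."""
    from .aif import evaluate_aif
    pd.DataFrame({"time_s": np.asarray(time_s, dtype=float),
                  "cp_mM": evaluate_aif(aif, time_s)}).to_csv(path, index=False)


def make_phantom_command(cfg: dict, outdir) -> list:
    """Generate the configured phantom cohort and write each subject."""
    outdir = Path(outdir)
    acq, aif, phantom, _, _, _ = build_params(cfg)
    seed = int(cfg.get("seed", phantom.seed))
    n_subjects = int(cfg.get("n_subjects", 1))
    sigma_mm = cfg.get("noise_sigma_mm")
    if sigma_mm is not None:
        phantom = replace(phantom, noise_sigma=signal_sigma_for_concentration(
            phantom, acq, float(sigma_mm)))
    if n_subjects == 1:
        studies = [simulate_study(replace(phantom, seed=seed), aif, acq)]
    else:
        studies = make_cohort(n_subjects, seed, phantom, aif, acq)
    _manifest(outdir, cfg, seed)
    aif_t = replace(aif, t0=phantom.arrival_index * phantom.dt)
    export_aif_curve(aif_t, phantom.time, outdir / "aif_curve.csv")
    dirs = []
    for i, st in enumerate(studies):
        sub = outdir / f"subject{i:02d}"
        write_phantom_study(st, sub, acq)
        dirs.append(sub)
    return dirs


# ------------------------------------------------- synthetic k-fold study

def synthetic_kfold_study(master_seed: int = 42, outdir=None,
                          parameter: str = "ktrans",
                          noise_sigma_mm: float = 0.01,
                          n_subjects: int = 6) -> dict:
    """Full synthetic leave-one-subject-out CNN study at desk scale.

    Generates a seeded phantom cohort (64 x 64 in-plane, 2 slices and 1-2
    heterogeneous lesions per subject, 40 dynamics, Rician noise at the
    concentration-equivalent ``noise_sigma_mm``), fits extended-Tofts
    target maps through the conventional pipeline (arrival detection, VFA
    T10, concentration conversion, voxelwise NLLS), then trains the
    reduced dual-pathway network leave-one-subject-out on the requested
    target parameter and evaluates held-out intratumoral agreement.

    Returns the :func:`run_cnn_pipeline` result dict (per-fold reports,
    pooled ensemble report, median intratumoral nRMSE).
    """
    import tempfile

    acq = AcquisitionParams()
    aif = AIFParams()
    base = PhantomSpec()
    base = replace(base, noise_sigma=signal_sigma_for_concentration(
        base, acq, noise_sigma_mm))
    cohort = make_cohort(n_subjects, master_seed, base, aif, acq)

    subjects_data = []
    for st in cohort:
        maps, _t1map, _conc, _arrival = pk_pipeline(
            st.dynamic, st.vfa, acq, aif, models=("extofts",))
        subjects_data.append({
            "signal": st.dynamic.signal,
            "mask": st.brain_mask,
            "lesion_mask": st.lesion_mask,
            "target": getattr(maps["extofts"], parameter),
        })

    cfg = {
        "network": {"profile": "reduced"},
        "train": {"lr": 1e-4, "l2": 1e-4, "max_epochs": 60, "minibatch": 4,
                  "val_every": 2, "patience": 10},
        "seed": int(master_seed),
    }
    if outdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return run_cnn_pipeline(cfg, tmp, subjects_data)
    return run_cnn_pipeline(cfg, outdir, subjects_data)
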