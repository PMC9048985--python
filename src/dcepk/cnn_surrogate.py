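"""Dual-pathway convolutional network predicting PK maps from DCE dynamics.

The network treats PK parameter estimation as an image-to-image mapping:
its input is the normalized 40-frame dynamic series of one slice (40
channels) and its output is a single-parameter map of the same in-plane
size.  A stem convolution extracts per-channel low-level features; two
parallel pathways then process them — a *local* pathway of three plain
4x4 convolutions resolving fine intratumoral detail, and a *global*
pathway of three 4x4 convolutions dilated by 2, 4 and 8 whose growing
receptive field captures context and overall structure.  The pathway
outputs (128 feature maps each at full scale) are concatenated and fed
to a stack of 1x1 convolutions — per-pixel fully connected layers of
1024, 512, 128 and 1 nodes — ending in a linear regression output.
Every convolution is zero-padded to preserve spatial size and every
layer but the last is followed by a ReLU.

Training minimizes masked per-voxel squared error with an L2 weight
penalty under Adam, with periodic validation checks and early stopping;
cross-validation follows a leave-one-subject-out rotation in which one
slice of each remaining subject is held out for validation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .nn import Adam, Conv2D, DepthwiseConv2D, ReLU
from .evaluation import agreement

__all__ = [
    "NetworkSpec", "TrainSpec", "FoldPlan", "TrainedModel",
    "build_network", "architecture_summary", "preprocess_for_net",
    "train_fold", "predict", "make_fold_plan", "run_kfold",
    "save_model", "load_model",
]


@dataclass
class NetworkSpec:
    """Architecture of the dual-pathway network.

    Defaults are the full-scale design (128 stem/pathway filters, head of
    1024/512/128/1 nodes); :meth:`reduced` gives a desk-scale profile for
    small synthetic cohorts.
    """

    in_channels: int = 40
    stem_filters: int = 128
    kernel_size: int = 4
    dilations: tuple = (2, 4, 8)
    n_local_layers: int = 3
    fc_nodes: tuple = (1024, 512, 128, 1)
    stem_mode: str = "depthwise"  # depthwise-separable stem, or "standard"

    def __post_init__(self):
        if self.stem_mode not in ("depthwise", "standard"):
            raise ValueError("stem_mode must be 'depthwise' or 'standard'")
        if self.fc_nodes[-1] != 1:
            raise ValueError("final head layer must have one node")

    @classmethod
    def reduced(cls, in_channels: int = 40) -> "NetworkSpec":
        return cls(in_channels=in_channels, stem_filters=32,
                   fc_nodes=(256, 128, 64, 1))


@dataclass
class TrainSpec:
    """Optimization protocol: Adam, lr 1e-4, L2 1e-4, minibatch 20,
    at most 600 epochs, validation checks every 2 iterations with early
    stopping after ``patience`` non-improving checks."""

    lr: float = 1e-4
    l2: float = 1e-4
    max_epochs: int = 600
    minibatch: int = 20
    val_every: int = 2
    patience: int = 10
    seed: int = 0
    normalize_target: bool = True

    def __post_init__(self):
        for name in ("max_epochs", "minibatch", "val_every", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.l2 < 0 or self.lr < 0:
            raise ValueError("lr and l2 must be nonnegative")


class DualPathwayNet:
    """Stem -> (local || global dilated) -> concat -> 1x1 head."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        f = spec.stem_filters
        k = spec.kernel_size
        self.spec = spec
        if spec.stem_mode == "depthwise":
            self.stem = [DepthwiseConv2D(spec.in_channels, k=k, rng=rng),
                         Conv2D(spec.in_channels, f, k=1, rng=rng), ReLU()]
        else:
            self.stem = [Conv2D(spec.in_channels, f, k=k, rng=rng), ReLU()]
        self.local = []
        for _ in range(spec.n_local_layers):
            self.local += [Conv2D(f, f, k=k, dilation=1, rng=rng), ReLU()]
        self.global_ = []
        for d in spec.dilations:
            self.global_ += [Conv2D(f, f, k=k, dilation=d, rng=rng), ReLU()]
        self.head = []
        cin = 2 * f
        for i, nodes in enumerate(spec.fc_nodes):
            conv = Conv2D(cin, nodes, k=1, rng=rng)
            if i == len(spec.fc_nodes) - 1:
                # zero-init the regression output so the initial prediction
                # is the (normalized) target mean; stabilizes short schedules
                conv.w[...] = 0.0
            self.head.append(conv)
            if i < len(spec.fc_nodes) - 1:
                self.head.append(ReLU())
            cin = nodes

    # -- plumbing -----------------------------------------------------
    def layers(self):
        return self.stem + self.local + self.global_ + self.head

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def weight_norm(self) -> float:
        return float(np.sqrt(sum((v ** 2).sum() for n, v, _ in self.params()
                                 if n == "w")))

    def forward(self, x, train=True):
        h = x.astype(np.float32, copy=False)
        for layer in self.stem:
            h = layer.forward(h, train=train)
        hl = h
        for layer in self.local:
            hl = layer.forward(hl, train=train)
        hg = h
        for layer in self.global_:
            hg = layer.forward(hg, train=train)
        c = np.concatenate([hl, hg], axis=-1)
        y = c
        for layer in self.head:
            y = layer.forward(y, train=train)
        return y

    def backward(self, grad):
        g = grad
        for layer in reversed(self.head):
            g = layer.backward(g)
        f = self.spec.stem_filters
        gl, gg = g[..., :f], g[..., f:]
        for layer in reversed(self.local):
            gl = layer.backward(gl)
        for layer in reversed(self.global_):
            gg = layer.backward(gg)
        g = gl + gg
        for layer in reversed(self.stem):
            g = layer.backward(g)
        return g

    def get_weights(self):
        return [[v.copy() for _, v, _ in layer.params()] for layer in self.layers()]

    def set_weights(self, weights):
        for layer, ws in zip(self.layers(), weights):
            for (_, v, _), w in zip(layer.params(), ws):
                v[...] = w


def build_network(spec: NetworkSpec, seed: int = 0) -> DualPathwayNet:
    """Instantiate the dual-pathway network with seeded He initialization."""
    return DualPathwayNet(spec, np.random.default_rng(seed))


def architecture_summary(net: DualPathwayNet) -> dict:
    """Programmatic audit of the composed model graph.

    Walks the layer lists and reports filter counts, kernel sizes,
    dilations and head widths, plus a shape probe confirming the
    size-preserving H x W x 1 output contract.
    """
    spec = net.spec
    convs = [l for l in net.layers() if isinstance(l, (Conv2D, DepthwiseConv2D))]
    local_convs = [l for l in net.local if isinstance(l, Conv2D)]
    global_convs = [l for l in net.global_ if isinstance(l, Conv2D)]
    head_convs = [l for l in net.head if isinstance(l, Conv2D)]
    probe = np.zeros((1, 12, 16, spec.in_channels), dtype=np.float32)
    out = net.forward(probe, train=False)
    n_params = sum(v.size for _, v, _ in net.params())
    return {
        "stem_filters": net.stem[-2].cout if spec.stem_mode == "depthwise"
        else net.stem[0].cout,
        "stem_kernel": net.stem[0].k,
        "pathway_kernels": sorted({l.k for l in local_convs + global_convs}),
        "local_filters": [l.cout for l in local_convs],
        "local_dilations": [l.dilation for l in local_convs],
        "global_filters": [l.cout for l in global_convs],
        "global_dilations": [l.dilation for l in global_convs],
        "concat_channels": head_convs[0].cin,
        "head_nodes": [l.cout for l in head_convs],
        "head_kernels": [l.k for l in head_convs],
        "n_layers": len(net.layers()),
        "n_conv_layers": len(convs),
        "n_parameters": int(n_params),
        "output_shape": tuple(out.shape[1:]),
        "preserves_size": out.shape[1:3] == probe.shape[1:3] and out.shape[3] == 1,
    }


def preprocess_for_net(signal: np.ndarray, mask: np.ndarray,
                       smooth_sigma: float = 0.0, n_dynamics: int = 40) -> np.ndarray:
    """Normalize one subject's dynamic stack into network input tensors.

    ``signal`` is (row, col, frame, slice) and ``mask`` (row, col, slice).
    Steps: optional 3-D Gaussian smoothing over (row, col, slice) per
    frame; truncation to the first ``n_dynamics`` frames; masking out
    skull/peripheral voxels; per-plane standardization — every
    (slice, frame) plane is scaled to zero mean and unit variance over
    its masked voxels (constant planes map to zero).

    Returns a float32 tensor of shape (n_slices, row, col, n_dynamics).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 4:
        raise ValueError("signal must be (row, col, frame, slice)")
    if signal.shape[2] < n_dynamics:
        raise ValueError(f"need at least {n_dynamics} dynamics")
    sig = signal[:, :, :n_dynamics, :]
    if smooth_sigma > 0:
        sig = np.stack([gaussian_filter(sig[:, :, t, :], sigma=smooth_sigma)
                        for t in range(n_dynamics)], axis=2)
    out = np.zeros((sig.shape[3], sig.shape[0], sig.shape[1], n_dynamics),
                   dtype=np.float32)
    for s in range(sig.shape[3]):
        m = mask[:, :, s] if mask.ndim == 3 else mask
        for t in range(n_dynamics):
            plane = sig[:, :, t, s]
            vals = plane[m]
            sd = vals.std()
            if vals.size and sd > 1e-12:
                norm = (plane - vals.mean()) / sd
            else:
                norm = np.zeros_like(plane)
            out[s, :, :, t] = np.where(m, norm, 0.0)
    return out


@dataclass
class TrainedModel:
    """A trained network plus the target scaling needed to undo it."""

    net: DualPathwayNet
    nspec: NetworkSpec
    tspec: TrainSpec
    target_mean: float
    target_sd: float
    history: pd.DataFrame


def _masked_mse(pred, target, mask):
    n = mask.sum()
    if n == 0:
        return 0.0, np.zeros_like(pred)
    diff = np.where(mask, pred - target, 0.0)
    loss = float((diff ** 2).sum() / n)
    return loss, (2.0 / n) * diff


def train_fold(train_x, train_y, train_mask, val_x, val_y, val_mask,
               tspec: TrainSpec, nspec: NetworkSpec) -> TrainedModel:
    """Train one network on (input stack, target map) pairs.

    Arrays are (n_samples, H, W, C) inputs and (n_samples, H, W) targets /
    boolean masks.  Optimizes masked mean squared error + L2 penalty with
    Adam; validation loss is checked every ``val_every`` iterations and
    the best-validation weights are restored at the end (early stopping
    after ``patience`` non-improving checks).
    """
    train_x = np.asarray(train_x, dtype=np.float32)
    if train_x.shape[0] == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tspec.seed)
    net = DualPathwayNet(nspec, rng)

    if tspec.normalize_target:
        vals = train_y[train_mask]
        mu = float(vals.mean()) if vals.size else 0.0
        sd = float(vals.std()) if vals.size and vals.std() > 1e-12 else 1.0
    else:
        mu, sd = 0.0, 1.0
    ty = ((train_y - mu) / sd).astype(np.float32)
    vy = ((val_y - mu) / sd).astype(np.float32) if val_x is not None else None

    opt = Adam(net.params(), lr=tspec.lr, l2=tspec.l2)
    n = train_x.shape[0]
    best_val, best_weights, bad_checks = np.inf, None, 0
    history = []
    iteration = 0
    stop = False

    def val_loss():
        if val_x is None or val_x.shape[0] == 0:
            return np.nan
        pred = net.forward(val_x, train=False)[..., 0]
        return _masked_mse(pred, vy, val_mask)[0]

    for epoch in range(tspec.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, tspec.minibatch):
            sel = order[start:start + tspec.minibatch]
            xb, yb, mb = train_x[sel], ty[sel], train_mask[sel]
            pred = net.forward(xb, train=True)[..., 0]
            loss, dpred = _masked_mse(pred, yb, mb)
            net.backward(dpred[..., np.newaxis].astype(np.float32))
            opt.step()
            iteration += 1
            vl = np.nan
            if iteration % tspec.val_every == 0:
                vl = val_loss()
                if np.isfinite(vl) and vl < best_val - 1e-12:
                    best_val, best_weights, bad_checks = vl, net.get_weights(), 0
                elif np.isfinite(vl):
                    bad_checks += 1
                    if bad_checks >= tspec.patience:
                        stop = True
            history.append({"iteration": iteration, "epoch": epoch,
                            "train_loss": loss, "val_loss": vl})
            if stop:
                break
        if stop:
            break
    if best_weights is not None:
        net.set_weights(best_weights)
    return TrainedModel(net=net, nspec=nspec, tspec=tspec, target_mean=mu,
                        target_sd=sd, history=pd.DataFrame(history))


def predict(model: TrainedModel, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Single deterministic forward pass; output masked like the input.

    ``x`` is (n_samples, H, W, C); returns (n_samples, H, W) maps in the
    target's original units, zero outside the mask.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.shape[-1] != model.nspec.in_channels:
        raise ValueError("channel count does not match the trained network")
    pred = model.net.forward(x, train=False)[..., 0]
    pred = pred * model.target_sd + model.target_mean
    return np.where(mask, pred, 0.0)


@dataclass
class FoldPlan:
    """Leave-one-subject-out rotation with per-subject validation slices.

    ``folds`` entries are dicts with keys ``test_subject``, ``val``
    (list of (subject, slice)), ``train`` (list of (subject, slice)).
    """

    n_subjects: int
    n_slices: int
    folds: list = field(default_factory=list)

    def validate(self):
        tested = [f["test_subject"] for f in self.folds]
        if sorted(tested) != list(range(self.n_subjects)):
            raise ValueError("each subject must be held out exactly once")
        for f in self.folds:
            t = f["test_subject"]
            train_subj = {s for s, _ in f["train"]}
            val_subj = {s for s, _ in f["val"]}
            if t in train_subj or t in val_subj:
                raise ValueError("test subject leaked into train/val")
            if self.n_slices > 1 and not val_subj <= train_subj:
                raise ValueError("validation outside training subjects")
            if set(f["train"]) & set(f["val"]):
                raise ValueError("train/val slice overlap")


def make_fold_plan(n_subjects: int, n_slices: int, seed: int = 0) -> FoldPlan:
    """One fold per held-out subject; validation = one random slice from
    each remaining subject, the rest of their slices train."""
    if n_subjects < 2:
        raise ValueError("k-fold rotation needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    plan = FoldPlan(n_subjects=n_subjects, n_slices=n_slices)
    for test in range(n_subjects):
        val, train = [], []
        for subj in range(n_subjects):
            if subj == test:
                continue
            v = int(rng.integers(n_slices))
            for sl in range(n_slices):
                (val if sl == v else train).append((subj, sl))
        plan.folds.append({"test_subject": test, "val": val, "train": train})
    plan.validate()
    return plan


def _gather(inputs, targets, masks, pairs):
    x = np.stack([inputs[s][sl] for s, sl in pairs])
    y = np.stack([targets[s][:, :, sl] for s, sl in pairs])
    m = np.stack([masks[s][:, :, sl] for s, sl in pairs])
    return x, y, m


def run_kfold(inputs, targets, masks, lesion_masks, plan: FoldPlan,
              nspec: NetworkSpec, tspec: TrainSpec, seed: int = 0) -> dict:
    """Leave-one-subject-out training/evaluation of one PK parameter.

    Parameters
    ----------
    inputs : list of (n_slices, H, W, C) preprocessed stacks, one per subject.
    targets : list of (H, W, n_slices) target parameter maps.
    masks : list of (H, W, n_slices) brain masks (training loss support).
    lesion_masks : list of (H, W, n_slices) intratumoral masks (evaluation).
    plan : FoldPlan from :func:`make_fold_plan`.

    Returns a dict with per-fold trained models, held-out predictions,
    intratumoral agreement reports, and the pooled (ensemble) report.
    """
    plan.validate()
    folds_out = []
    pooled_pred, pooled_targ = [], []
    for k, fold in enumerate(plan.folds):
        tx, ty, tm = _gather(inputs, targets, masks, fold["train"])
        vx, vy, vm = _gather(inputs, targets, masks, fold["val"])
        fold_tspec = TrainSpec(**{**asdict(tspec), "seed": seed + 1000 * k})
        model = train_fold(tx, ty, tm, vx, vy, vm, fold_tspec, nspec)

        test = fold["test_subject"]
        test_mask = np.moveaxis(masks[test], -1, 0)
        pred = predict(model, inputs[test], test_mask)
        pred_map = np.moveaxis(pred, 0, -1)
        lm = lesion_masks[test] & masks[test]
        report = agreement(pred_map, targets[test], lm)
        folds_out.append({"fold": k, "test_subject": test, "model": model,
                          "prediction": pred_map, "report": report})
        pooled_pred.append(pred_map[lm])
        pooled_targ.append(targets[test][lm])
    ensemble = agreement(np.concatenate(pooled_pred), np.concatenate(pooled_targ),
                         np.ones(sum(p.size for p in pooled_pred), dtype=bool))
    nrmses = np.array([f["report"].nrmse for f in folds_out])
    return {"folds": folds_out, "ensemble": ensemble,
            "median_nrmse": float(np.median(nrmses)),
            "nrmse_per_fold": nrmses}


def save_model(model: TrainedModel, path: str):
    """Checkpoint: weight arrays in .npz plus a JSON sidecar of the specs."""
    arrays = {}
    for i, ws in enumerate(model.net.get_weights()):
        for j, w in enumerate(ws):
            arrays[f"layer{i}_p{j}"] = w
    np.savez(path, **arrays)
    side = {"network": asdict(model.nspec), "train": asdict(model.tspec),
            "target_mean": model.target_mean, "target_sd": model.target_sd}
    with open(str(path) + ".json", "w") as fh:
        json.dump(side, fh, indent=2, default=list)


def load_model(path: str) -> TrainedModel:
    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    nspec = NetworkSpec(**{**side["network"],
                           "dilations": tuple(side["network"]["dilations"]),
                           "fc_nodes": tuple(side["network"]["fc_nodes"])})
    tspec = TrainSpec(**side["train"])
    net = build_network(nspec, seed=0)
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    weights = []
    for i, layer in enumerate(net.layers()):
        ws = []
        for j, _ in enumerate(layer.params()):
            ws.append(data[f"layer{i}_p{j}"])
        weights.append(ws)
    net.set_weights(weights)
    return TrainedModel(net=net, nspec=nspec, tspec=tspec,
                        target_mean=side["target_mean"],
                        target_sd=side["target_sd"], history=pd.DataFrame())
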