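"""Training and inference orchestration.

Training follows a two-stage recipe.  Stage 1 optimizes the backbone,
both decoder parsers and the refinement with the weighted total loss
``L = L_mse + lambda * L_bce + gamma * L_si`` on randomly cropped,
flipped and gamma-jittered patches, with density/attention targets built
on the fly at half the crop resolution and the positive–negative loss
taking the crop-local count as its target.  Stage 2 trains the size head
(fine-tuning the backbone) with an L1 loss against each image's
KNN pseudo-average plant size.

All randomness — weight init, data order, crop position, flip and gamma
decisions — flows from the single ``TrainConfig.seed`` through per-
consumer child generators, so reruns with an identical config are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import losses
from .groundtruth import (DensityGrid, SizeUndefinedError, make_attention_gt,
                          make_density_map, pseudo_mean_size)
from .io import DetectionTable, PointSet
from .localization import LNMSParams, lnms, match_points
from .network import CountingNet, preprocess
from .nn import Adam
from .evaluation import CountPairs, count_from_density, mae, r_squared, rmse
from .sizing import SizingParams, fuse_sizes, knn_sizes, make_detections

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """All hyperparameters of the training/inference recipe.

    Defaults follow the full-scale recipe: Gaussian target sd 6, 320 px
    crops, horizontal flip p=0.5, gamma-contrast p=0.3 with exponents in
    [0.5, 2], Adam at 1e-4 with batch size 3, loss weights lambda=0.1 and
    gamma=0.1, positive probability p=1, K=3 neighbours with beta=0.8.
    The ``tiny`` architecture preset used for CPU-scale runs pairs with a
    larger learning rate (see docs/methods.md).
    """

    sigma: float = 6.0
    crop_size: int = 320
    flip_prob: float = 0.5
    gamma_prob: float = 0.3
    gamma_range: tuple[float, float] = (0.5, 2.0)
    learning_rate: float = 1e-4
    batch_size: int = 3
    lambda_bce: float = 0.1
    gamma_si: float = 0.1
    p_pos: float = 1.0
    k_neighbors: int = 3
    beta: float = 0.8
    fallback_size: float = 8.0
    stage1_iters: int = 2000
    stage2_iters: int = 600
    stage2_learning_rate: float | None = None  # defaults to learning_rate
    val_every: int = 250
    seed: int = 0
    architecture: str = "tiny"
    lnms: LNMSParams = field(default_factory=LNMSParams)

    def __post_init__(self):
        for p in (self.flip_prob, self.gamma_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        if self.crop_size % 16:
            raise ValueError("crop_size must be a multiple of 16")
        if self.batch_size < 1 or self.stage1_iters < 0 or self.stage2_iters < 0:
            raise ValueError("counts must be positive")
        if not 0 < self.p_pos <= 1:
            raise ValueError("p_pos must be in (0,1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gamma_range"] = list(self.gamma_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "gamma_range" in d:
            d["gamma_range"] = tuple(d["gamma_range"])
        if isinstance(d.get("lnms"), dict):
            d["lnms"] = LNMSParams(**d["lnms"])
        return cls(**d)


def augment(image: np.ndarray, points: PointSet, cfg: TrainConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, PointSet]:
    """Random crop + horizontal flip + gamma contrast, with points mapped along.

    Images smaller than the crop are edge-padded first (with a warning).
    Points falling outside the crop are dropped; surviving points are
    re-origined to the crop frame.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    cs = cfg.crop_size
    if h < cs or w < cs:
        log.warning("image %dx%d smaller than crop %d; padding", h, w, cs)
        img = np.pad(img, ((0, max(cs - h, 0)), (0, max(cs - w, 0)), (0, 0)), mode="edge")
        h, w = img.shape[:2]
    y0 = int(rng.integers(0, h - cs + 1))
    x0 = int(rng.integers(0, w - cs + 1))
    crop = img[y0:y0 + cs, x0:x0 + cs].copy()
    pts = points.points
    if len(pts):
        keep = ((pts[:, 0] >= x0) & (pts[:, 0] < x0 + cs) &
                (pts[:, 1] >= y0) & (pts[:, 1] < y0 + cs))
        pts = pts[keep] - np.array([x0, y0], float)
    if rng.uniform() < cfg.flip_prob:
        crop = crop[:, ::-1].copy()
        if len(pts):
            # mirror about the pixel-center axis; the sub-pixel sliver beyond
            # cs-1 would map just below 0, clamp it onto the border
            pts = np.column_stack([np.maximum(cs - 1 - pts[:, 0], 0.0), pts[:, 1]])
    if rng.uniform() < cfg.gamma_prob:
        exponent = rng.uniform(*cfg.gamma_range)
        crop = (np.clip(crop / 255.0, 0, 1) ** exponent * 255.0).astype(crop.dtype)
    return crop, PointSet(np.asarray(pts, float).reshape(-1, 2))


@dataclass
class Checkpoint:
    """A trained model plus the config and per-iteration loss history."""

    net: CountingNet
    cfg: TrainConfig
    history: dict = field(default_factory=dict)

    def save(self, path) -> None:
        self.net.save(path, extra={"train_config": self.cfg.to_dict(),
                                   "history": {k: list(map(float, v))
                                               for k, v in self.history.items()}})

    @classmethod
    def load(cls, path) -> "Checkpoint":
        net = CountingNet.load(path)
        sidecar = json.loads(Path(path).with_suffix(".json").read_text())
        cfg = TrainConfig.from_dict(sidecar["train_config"]) if "train_config" in sidecar \
            else TrainConfig()
        return cls(net, cfg, sidecar.get("history", {}))


def _make_batch(dataset, cfg: TrainConfig, rng: np.random.Generator):
    """Sample, augment and target-build one training batch."""
    idx = rng.integers(0, len(dataset), size=cfg.batch_size)
    xs, dens, atts, counts = [], [], [], []
    gshape = (cfg.crop_size // 2, cfg.crop_size // 2)
    for i in idx:
        img, pts = dataset[i]
        crop, cpts = augment(img, pts, cfg, rng)
        xs.append(preprocess(crop)[0])
        den = make_density_map(cpts, gshape, cfg.sigma)
        dens.append(den.values)
        atts.append(make_attention_gt(den).values)
        counts.append(float(len(cpts)))
    return (np.stack(xs), np.stack(dens), np.stack(atts), np.asarray(counts))


def _stage1_losses(out, dens, atts, counts, cfg: TrainConfig):
    """Total loss and the output-side gradients for one batch."""
    fdm, pam, logits = out["fdm"], out["pam"], out["pam_logits"]
    n = fdm.shape[0]
    l_mse = losses.mse_loss(fdm, dens)
    l_bce = losses.bce_loss(pam, atts)
    d_fdm = losses.mse_grad(fdm, dens)
    d_logits = cfg.lambda_bce * losses.bce_grad_wrt_logits(pam, atts)
    l_si = 0.0
    if cfg.gamma_si > 0:
        g_si = np.zeros_like(fdm)
        for i in range(n):
            l_si += losses.pn_loss(fdm[i], dens[i], counts[i], cfg.p_pos)
            g_si[i] = losses.pn_grad(fdm[i], dens[i], counts[i], cfg.p_pos)
        l_si /= n
        d_fdm = d_fdm + cfg.gamma_si * g_si / n
    total = losses.total_loss(l_mse, l_bce, l_si, cfg.lambda_bce, cfg.gamma_si)
    return total, l_mse, l_bce, l_si, d_fdm, d_logits


def _val_mae(net: CountingNet, val_dataset, cfg: TrainConfig) -> float:
    truths, preds = [], []
    for img, pts in val_dataset:
        fdm = net.predict_maps(np.asarray(img))[2]
        truths.append(len(pts))
        preds.append(count_from_density(fdm))
    return mae(CountPairs(truths, preds))


def train_stage1(dataset, cfg: TrainConfig, net: CountingNet | None = None,
                 val_dataset=None) -> Checkpoint:
    """Stage 1: backbone + density/attention decoders with the total loss.

    ``dataset`` is a sequence of ``(image, PointSet)`` pairs.  If
    ``val_dataset`` is given, the count MAE on it is evaluated every
    ``cfg.val_every`` iterations and the best-scoring weights are
    restored at the end; otherwise the final weights are returned.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    if net is None:
        net_seed = int(np.random.SeedSequence(cfg.seed, spawn_key=(0,)).generate_state(1)[0] % (2**31))
        net = CountingNet(cfg.architecture, seed=net_seed)
    opt = Adam(net.stage1_params(), lr=cfg.learning_rate)
    history = {"total": [], "mse": [], "bce": [], "si": []}
    best = None
    for it in range(cfg.stage1_iters):
        xs, dens, atts, counts = _make_batch(dataset, cfg, rng)
        out = net.forward(xs, train=True)
        total, l_mse, l_bce, l_si, d_fdm, d_logits = _stage1_losses(out, dens, atts, counts, cfg)
        opt.zero_grad()
        net.backward(d_fdm=d_fdm, d_pam_logits=d_logits)
        opt.step()
        history["total"].append(total)
        history["mse"].append(l_mse)
        history["bce"].append(l_bce)
        history["si"].append(l_si)
        if val_dataset is not None and (it + 1) % cfg.val_every == 0:
            v = _val_mae(net, val_dataset, cfg)
            log.info("stage1 iter %d: loss %.4f, val MAE %.3f", it + 1, total, v)
            if best is None or v < best[0]:
                best = (v, {k: a.copy() for k, a in net.state_dict().items()})
        elif (it + 1) % 100 == 0:
            log.info("stage1 iter %d: loss %.4f", it + 1, total)
    if best is not None:
        for name, lyr in net._named_layers():
            lyr.load_state({k[len(name) + 1:]: v for k, v in best[1].items()
                            if k.startswith(name + ".")})
        history["best_val_mae"] = [best[0]]
    return Checkpoint(net, cfg, history)


def train_stage2(dataset, checkpoint: Checkpoint, cfg: TrainConfig | None = None) -> Checkpoint:
    """Stage 2: size head + backbone fine-tuning with L1 pseudo-size loss.

    Images with fewer than ``k_neighbors + 1`` points are skipped (with a
    warning).  With ``stage2_iters == 0`` the checkpoint is returned
    unchanged except for metadata.
    """
    cfg = cfg or checkpoint.cfg
    # work on a copy so the stage-1 checkpoint remains usable as-is
    net = CountingNet(checkpoint.net.architecture, mean=checkpoint.net.mean,
                      std=checkpoint.net.std)
    for (_, dst), (_, src) in zip(net._named_layers(), checkpoint.net._named_layers()):
        dst.load_state({k: v.copy() for k, v in src.state().items()})
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    usable, targets = [], []
    for img, pts in dataset:
        try:
            targets.append(pseudo_mean_size(pts, cfg.k_neighbors, cfg.beta))
            usable.append((np.asarray(img), pts))
        except SizeUndefinedError:
            log.warning("skipping image with %d points (< k+1 = %d)",
                        len(pts), cfg.k_neighbors + 1)
    if not usable and cfg.stage2_iters > 0:
        raise ValueError("no image has enough points for stage-2 size targets")
    history = dict(checkpoint.history)
    history["size_l1"] = []
    if cfg.stage2_iters == 0:
        return Checkpoint(net, cfg, history)
    opt = Adam(net.stage2_params(), lr=cfg.stage2_learning_rate or cfg.learning_rate)
    nb = min(cfg.batch_size, len(usable))
    for it in range(cfg.stage2_iters):
        idx = rng.integers(0, len(usable), size=nb)
        xs = np.concatenate([preprocess(usable[i][0]) for i in idx])
        tgt = np.asarray([targets[i] for i in idx])
        d_p = net.forward_pse(xs, train=True)
        l1 = float(np.mean(np.abs(d_p - tgt)))
        opt.zero_grad()
        net.backward(d_dp=np.sign(d_p - tgt) / nb)
        opt.step()
        history["size_l1"].append(l1)
        if (it + 1) % 100 == 0:
            log.info("stage2 iter %d: L1 %.4f (d_p %.3f)", it + 1, l1, float(d_p.mean()))
    return Checkpoint(net, cfg, history)


@dataclass
class PredictResult:
    count: float
    detections: DetectionTable
    fdm: DensityGrid
    pam: object
    d_p: float
    detection_count: int


def predict(image: np.ndarray, checkpoint: Checkpoint,
            cfg: TrainConfig | None = None, d_mean: float | None = None) -> PredictResult:
    """Counting, locating and sizing for one image.

    The count is the integral of the refined density map; plant centers
    come from LNMS; per-plant sizes fuse KNN distances between detections
    with the regressed limit ``d_p``.  ``d_mean`` (image pixels) overrides
    the regressed size for the LNMS window — used when evaluating against
    annotated data; by default the size head's output is used, falling
    back to ``cfg.fallback_size`` if the head is untrained (outputs 0).
    """
    cfg = cfg or checkpoint.cfg
    net = checkpoint.net
    idm, pam, fdm, d_p = net.predict_maps(np.asarray(image))
    count = count_from_density(fdm)
    size_ref = d_mean if d_mean is not None else (d_p if d_p > 0 else cfg.fallback_size)
    centers = lnms(fdm, size_ref / fdm.scale, cfg.lnms)
    sizing = SizingParams(cfg.k_neighbors, cfg.beta, cfg.fallback_size)
    d_cap = d_p if d_p > 0 else cfg.fallback_size
    sizes = fuse_sizes(knn_sizes(centers, sizing), d_cap)
    dets = make_detections(centers, sizes)
    return PredictResult(count, dets, fdm, pam, d_p, len(dets))


def evaluate_dataset(checkpoint: Checkpoint, dataset, cfg: TrainConfig | None = None,
                     radius: float | None = None):
    """Counting + localization metrics over an annotated dataset.

    The LNMS window uses each image's annotation-derived pseudo-size;
    the match radius defaults to half that size per image.  Returns
    (per-image rows, summary dict).
    """
    cfg = cfg or checkpoint.cfg
    rows, truths, preds = [], [], []
    hits_t = miss_t = fa_t = 0
    for i, (img, pts) in enumerate(dataset):
        try:
            dm = pseudo_mean_size(pts, cfg.k_neighbors, cfg.beta)
        except SizeUndefinedError:
            dm = cfg.fallback_size
        res = predict(img, checkpoint, cfg, d_mean=dm)
        r = radius if radius is not None else dm / 2.0
        hits, misses, fas = match_points(
            PointSet(res.detections.xy), pts, max(r, 1e-9))
        hits_t, miss_t, fa_t = hits_t + hits, miss_t + misses, fa_t + fas
        truths.append(float(len(pts)))
        preds.append(res.count)
        rows.append({"image": i, "truth": len(pts), "predicted": res.count,
                     "detections": res.detection_count, "hits": hits,
                     "misses": misses, "false_alarms": fas})
    pairs = CountPairs(truths, preds)
    summary = {
        "mae": mae(pairs), "rmse": rmse(pairs),
        "relative_mae": mae(pairs) / max(np.mean(truths), 1e-9),
        "recall": hits_t / max(hits_t + miss_t, 1),
        "precision": hits_t / max(hits_t + fa_t, 1),
    }
    for mode in ("as_printed", "standard"):
        try:
            summary[f"r2_{mode}"] = r_squared(pairs, mode)
        except ValueError:
            summary[f"r2_{mode}"] = float("nan")
    return rows, summary


def render_overlay(image: np.ndarray, detections: DetectionTable) -> np.ndarray:
    """Red center dots and white square boxes over the input image."""
    img = np.asarray(image).astype(np.uint8).copy()
    h, w = img.shape[:2]
    for (x, y), s in zip(detections.xy, detections.sizes):
        xi, yi = int(round(x)), int(round(y))
        half = max(int(round(s / 2)), 1)
        x0, x1 = max(xi - half, 0), min(xi + half, w - 1)
        y0, y1 = max(yi - half, 0), min(yi + half, h - 1)
        img[y0, x0:x1 + 1] = img[y1, x0:x1 + 1] = (255, 255, 255)
        img[y0:y1 + 1, x0] = img[y0:y1 + 1, x1] = (255, 255, 255)
        img[max(yi - 1, 0):yi + 2, max(xi - 1, 0):xi + 2] = (255, 0, 0)
    return img
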