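"""The plant counting network.

A VGG-16-with-batch-norm style encoder (13 convolutions in five blocks)
produces a four-level feature pyramid L1..L4 at strides 2/4/8/16.  Two
structurally identical decoders walk back up the pyramid by bilinear
upsampling and channel concatenation: the density branch (Parser 1,
Parser 2, density head) emits the initial density map IDM, and the
attention branch (Parser 3, Parser 4, attention head) emits the plant
attention map PAM, a per-cell plant-presence probability.  The refined
final density map is ``FDM = ReLU(Conv1x1(PAM ⊙ IDM))``.  A small size
head on L4 (two convolutions, adaptive pooling, two linear layers)
regresses the per-image plant-size limit ``d_p``.

IDM/PAM/FDM share one shape: half the (padded) input resolution.  Two
presets exist: ``full`` (VGG widths 64/128/256/512) and ``tiny`` (widths
divided by 8), the latter for CPU-speed training in tests; the topology
is identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .groundtruth import AttentionGrid, DensityGrid
from .nn import (AdaptiveAvgPool2d, Conv2d, ConvBNReLU, Linear, MaxPool2,
                 Param, ReLU, Sigmoid, Softplus, Upsample2x)

# per-channel normalization applied to [0,1] RGB before encoding
DEFAULT_MEAN = (0.485, 0.456, 0.406)
DEFAULT_STD = (0.229, 0.224, 0.225)

PRESETS = {"full": (64, 128, 256, 512), "tiny": (8, 16, 32, 64)}
MIN_INPUT = 32


class InputSizeError(ValueError):
    pass


def pad_to_multiple(batch: np.ndarray, multiple: int = 16) -> np.ndarray:
    """Zero-pad H and W (bottom/right) of an (N,H,W,C) batch to the next multiple."""
    h, w = batch.shape[1:3]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return batch
    return np.pad(batch, ((0, 0), (0, ph), (0, pw), (0, 0)))


def preprocess(image: np.ndarray, mean=DEFAULT_MEAN, std=DEFAULT_STD) -> np.ndarray:
    """HxWx3 uint8/float image -> normalized, padded (1,H',W',3) batch."""
    img = np.asarray(image, np.float32)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected HxWx3 image, got {img.shape}")
    img = img / 255.0
    img = (img - np.asarray(mean, np.float32)) / np.asarray(std, np.float32)
    return pad_to_multiple(img[None])


class _Branch:
    """One decoder branch: two parsers plus a head ending in a 1x1 conv."""

    def __init__(self, widths, rng):
        w1, w2, w3, w4 = widths
        self.up1, self.up2, self.up3 = Upsample2x(), Upsample2x(), Upsample2x()
        self.parser_a = [ConvBNReLU(w4 + w3, w3, rng), ConvBNReLU(w3, w3 // 2, rng)]
        self.parser_b = [ConvBNReLU(w3 // 2 + w2, w2, rng), ConvBNReLU(w2, w2 // 2, rng)]
        self.head = [ConvBNReLU(w2 // 2 + w1, w1, rng), ConvBNReLU(w1, w1 // 2, rng)]
        self.head_out = Conv2d(w1 // 2, 1, k=1, rng=rng)
        self._split = None

    def layers(self):
        return self.parser_a + self.parser_b + self.head + [self.head_out]

    def forward(self, l1, l2, l3, l4, train):
        a = np.concatenate([self.up1.forward(l4), l3], axis=3)
        for lyr in self.parser_a:
            a = lyr.forward(a, train)
        b = np.concatenate([self.up2.forward(a), l2], axis=3)
        for lyr in self.parser_b:
            b = lyr.forward(b, train)
        c = np.concatenate([self.up3.forward(b), l1], axis=3)
        for lyr in self.head:
            c = lyr.forward(c, train)
        self._split = (l4.shape[3], l3.shape[3], a.shape[3], l2.shape[3],
                       b.shape[3], l1.shape[3])
        return self.head_out.forward(c)

    def backward(self, gy):
        c4, c3, ca, c2, cb, c1 = self._split
        g = self.head_out.backward(gy)
        for lyr in reversed(self.head):
            g = lyr.backward(g)
        g_up, g_l1 = g[..., :-c1], g[..., -c1:]
        g = self.up3.backward(g_up)
        for lyr in reversed(self.parser_b):
            g = lyr.backward(g)
        g_up, g_l2 = g[..., :-c2], g[..., -c2:]
        g = self.up2.backward(g_up)
        for lyr in reversed(self.parser_a):
            g = lyr.backward(g)
        g_up, g_l3 = g[..., :-c3], g[..., -c3:]
        g_l4 = self.up1.backward(g_up)
        return g_l1, g_l2, g_l3, g_l4


class CountingNet:
    """Counting/locating/sizing model with explicit forward and backward."""

    def __init__(self, architecture: str = "full", seed: int = 0,
                 mean=DEFAULT_MEAN, std=DEFAULT_STD):
        if architecture not in PRESETS:
            raise ValueError(f"unknown architecture preset {architecture!r}")
        self.architecture = architecture
        self.mean, self.std = tuple(mean), tuple(std)
        w1, w2, w3, w4 = PRESETS[architecture]
        rng = np.random.default_rng(seed)

        self.block1 = [ConvBNReLU(3, w1, rng), ConvBNReLU(w1, w1, rng)]
        self.block2 = [ConvBNReLU(w1, w2, rng), ConvBNReLU(w2, w2, rng)]
        self.block3 = [ConvBNReLU(w2, w3, rng) ] + [ConvBNReLU(w3, w3, rng) for _ in range(2)]
        self.block4 = [ConvBNReLU(w3, w4, rng)] + [ConvBNReLU(w4, w4, rng) for _ in range(2)]
        self.block5 = [ConvBNReLU(w4, w4, rng) for _ in range(3)]
        self.pools = [MaxPool2() for _ in range(4)]

        self.density_branch = _Branch((w1, w2, w3, w4), rng)
        self.attention_branch = _Branch((w1, w2, w3, w4), rng)
        self.sigmoid = Sigmoid()
        self.idm_relu = ReLU()
        # refinement: identity-initialized 1x1 conv keeps FDM = PAM*IDM at start
        self.refine_conv = Conv2d(1, 1, k=1, rng=rng)
        self.refine_conv.w.value[...] = 1.0
        self.refine_conv.b.value[...] = 0.0
        self.refine_relu = ReLU()

        self.pse_convs = [ConvBNReLU(w4, w3, rng), ConvBNReLU(w3, w2, rng)]
        self.pse_pool = AdaptiveAvgPool2d(2)
        self.pse_fc1 = Linear(w2 * 4, w1, rng)
        self.pse_relu1 = ReLU()
        self.pse_fc2 = Linear(w1, 1, rng)
        self.pse_act = Softplus()

        self._cache = {}

    # ---------------- parameter bookkeeping ----------------

    def _named_layers(self):
        items = []
        for i, blk in enumerate([self.block1, self.block2, self.block3,
                                 self.block4, self.block5], start=1):
            for j, lyr in enumerate(blk):
                items.append((f"backbone.b{i}.{j}", lyr))
        for name, branch in [("dme", self.density_branch), ("att", self.attention_branch)]:
            for j, lyr in enumerate(branch.layers()):
                items.append((f"{name}.{j}", lyr))
        items.append(("refine", self.refine_conv))
        for j, lyr in enumerate(self.pse_convs):
            items.append((f"pse.conv{j}", lyr))
        items.append(("pse.fc1", self.pse_fc1))
        items.append(("pse.fc2", self.pse_fc2))
        return items

    def backbone_params(self) -> list[Param]:
        out = []
        for blk in [self.block1, self.block2, self.block3, self.block4, self.block5]:
            for lyr in blk:
                out += lyr.params()
        return out

    def stage1_params(self) -> list[Param]:
        out = self.backbone_params()
        for branch in [self.density_branch, self.attention_branch]:
            for lyr in branch.layers():
                out += lyr.params()
        out += self.refine_conv.params()
        return out

    def stage2_params(self) -> list[Param]:
        out = []
        for lyr in self.pse_convs:
            out += lyr.params()
        out += self.pse_fc1.params() + self.pse_fc2.params()
        return out + self.backbone_params()

    def all_params(self) -> list[Param]:
        seen, out = set(), []
        for _, lyr in self._named_layers():
            for p in lyr.params():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    # ---------------- forward ----------------

    def extract_features(self, x: np.ndarray, train: bool = False):
        """(N,H,W,3) normalized batch -> pyramid (L1, L2, L3, L4)."""
        h_in, w_in = x.shape[1:3]
        if h_in < MIN_INPUT or w_in < MIN_INPUT:
            raise InputSizeError(f"input {(h_in, w_in)} smaller than {MIN_INPUT}x{MIN_INPUT}")
        if h_in % 16 or w_in % 16:
            raise InputSizeError("input sides must be multiples of 16 (use pad_to_multiple)")
        h = x.astype(np.float32)
        for lyr in self.block1:
            h = lyr.forward(h, train)
        l1 = self.pools[0].forward(h)
        h = l1
        for lyr in self.block2:
            h = lyr.forward(h, train)
        l2 = self.pools[1].forward(h)
        h = l2
        for lyr in self.block3:
            h = lyr.forward(h, train)
        l3 = self.pools[2].forward(h)
        h = l3
        for lyr in self.block4:
            h = lyr.forward(h, train)
        h = self.pools[3].forward(h)
        for lyr in self.block5:
            h = lyr.forward(h, train)
        return l1, l2, l3, h

    def forward(self, x: np.ndarray, train: bool = False) -> dict:
        """Full forward pass; returns idm/pam_logits/pam/fdm/d_p arrays.

        Map outputs are (N, H/2, W/2); ``d_p`` is (N,).
        """
        l1, l2, l3, l4 = self.extract_features(x, train)
        idm_pre = self.density_branch.forward(l1, l2, l3, l4, train)
        idm = self.idm_relu.forward(idm_pre)
        pam_logits = self.attention_branch.forward(l1, l2, l3, l4, train)
        pam = self.sigmoid.forward(pam_logits)
        prod = pam * idm
        fdm = self.refine_relu.forward(self.refine_conv.forward(prod))

        d_p = self.pse_forward(l4, train)

        self._cache = {"idm": idm, "pam": pam}
        return {
            "idm": idm[..., 0], "pam_logits": pam_logits[..., 0], "pam": pam[..., 0],
            "fdm": fdm[..., 0], "d_p": d_p,
        }

    def dme_forward(self, fp, train: bool = False) -> np.ndarray:
        """Density branch only: pyramid -> IDM (N, H/2, W/2), non-negative."""
        l1, l2, l3, l4 = fp
        return self.idm_relu.forward(
            self.density_branch.forward(l1, l2, l3, l4, train))[..., 0]

    def attention_forward(self, fp, train: bool = False) -> np.ndarray:
        """Attention branch only: pyramid -> PAM probabilities in [0,1]."""
        l1, l2, l3, l4 = fp
        return self.sigmoid.forward(
            self.attention_branch.forward(l1, l2, l3, l4, train))[..., 0]

    def refine(self, idm: np.ndarray, pam: np.ndarray) -> np.ndarray:
        """FDM = ReLU(Conv1x1(PAM ⊙ IDM)) on (N,H,W) or (H,W) maps."""
        idm = np.asarray(idm, np.float32)
        pam = np.asarray(pam, np.float32)
        if idm.shape != pam.shape:
            raise ValueError(f"shape mismatch: {idm.shape} vs {pam.shape}")
        squeeze = idm.ndim == 2
        prod = (pam * idm)[None] if squeeze else (pam * idm)
        fdm = self.refine_relu.forward(self.refine_conv.forward(prod[..., None]))[..., 0]
        return fdm[0] if squeeze else fdm

    def pse_forward(self, l4: np.ndarray, train: bool = False) -> np.ndarray:
        """Size head only: L4 features -> non-negative per-image d_p (N,)."""
        h = l4
        for lyr in self.pse_convs:
            h = lyr.forward(h, train)
        h = self.pse_pool.forward(h)
        self._pse_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        z = self.pse_relu1.forward(self.pse_fc1.forward(flat))
        return self.pse_act.forward(self.pse_fc2.forward(z))[:, 0]

    def forward_pse(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Backbone + size head only (stage-2 training path); returns d_p (N,)."""
        _, _, _, l4 = self.extract_features(x, train)
        return self.pse_forward(l4, train)

    # ---------------- backward ----------------

    def backward(self, d_fdm=None, d_pam_logits=None, d_idm=None, d_dp=None):
        """Accumulate parameter gradients from output-side gradients.

        ``d_fdm``/``d_pam_logits``/``d_idm`` are (N,H/2,W/2) or None;
        ``d_dp`` is (N,) or None.  Gradients flow through the refinement
        into both branches and sum at the pyramid taps.
        """
        cache = self._cache
        g_l = [None, None, None, None]

        def add(i, g):
            g_l[i] = g if g_l[i] is None else g_l[i] + g

        if d_fdm is not None or d_pam_logits is not None or d_idm is not None:
            idm, pam = cache["idm"], cache["pam"]
            g_idm_total = np.zeros_like(idm)
            g_pam_total = np.zeros_like(pam)
            if d_idm is not None:
                g_idm_total += np.asarray(d_idm, np.float32)[..., None]
            if d_fdm is not None:
                g = self.refine_relu.backward(np.asarray(d_fdm, np.float32)[..., None])
                g_prod = self.refine_conv.backward(g)
                g_pam_total += g_prod * idm
                g_idm_total += g_prod * pam
            if np.any(g_idm_total):
                g = self.idm_relu.backward(g_idm_total)
                for i, gi in enumerate(self.density_branch.backward(g)):
                    add(i, gi)
            g_pam_logits = self.sigmoid.backward(g_pam_total)
            if d_pam_logits is not None:
                g_pam_logits = g_pam_logits + np.asarray(d_pam_logits, np.float32)[..., None]
            if np.any(g_pam_logits):
                for i, gi in enumerate(self.attention_branch.backward(g_pam_logits)):
                    add(i, gi)

        if d_dp is not None:
            g = np.asarray(d_dp, np.float32).reshape(-1, 1)
            g = self.pse_fc2.backward(self.pse_act.backward(g))
            g = self.pse_fc1.backward(self.pse_relu1.backward(g))
            g = g.reshape(self._pse_shape)
            g = self.pse_pool.backward(g)
            for lyr in reversed(self.pse_convs):
                g = lyr.backward(g)
            add(3, g)

        # backbone
        if g_l[3] is None:
            return
        g = g_l[3]
        for lyr in reversed(self.block5):
            g = lyr.backward(g)
        g = self.pools[3].backward(g)
        for lyr in reversed(self.block4):
            g = lyr.backward(g)
        if g_l[2] is not None:
            g = g + g_l[2]
        g = self.pools[2].backward(g)
        for lyr in reversed(self.block3):
            g = lyr.backward(g)
        if g_l[1] is not None:
            g = g + g_l[1]
        g = self.pools[1].backward(g)
        for lyr in reversed(self.block2):
            g = lyr.backward(g)
        if g_l[0] is not None:
            g = g + g_l[0]
        g = self.pools[0].backward(g)
        for lyr in reversed(self.block1):
            g = lyr.backward(g)

    # ---------------- convenience API ----------------

    def predict_maps(self, image: np.ndarray):
        """HxWx3 image -> (idm, pam, fdm, d_p) in eval mode, as grids."""
        x = preprocess(image, self.mean, self.std)
        out = self.forward(x, train=False)
        return (DensityGrid(out["idm"][0], scale=2),
                AttentionGrid(np.clip(out["pam"][0], 0, 1), scale=2),
                DensityGrid(out["fdm"][0], scale=2),
                float(out["d_p"][0]))

    # ---------------- checkpoints ----------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, lyr in self._named_layers():
            for k, v in lyr.state().items():
                out[f"{name}.{k}"] = v
        return out

    def save(self, path, extra: dict | None = None) -> None:
        """Weights as .npz plus a JSON sidecar with the architecture preset."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        sidecar = {"architecture": self.architecture, "mean": self.mean, "std": self.std}
        if extra:
            sidecar.update(extra)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "CountingNet":
        path = Path(path)
        try:
            sidecar = json.loads(path.with_suffix(".json").read_text())
        except FileNotFoundError as exc:
            raise IOError(f"missing checkpoint sidecar for {path}") from exc
        net = cls(architecture=sidecar["architecture"],
                  mean=sidecar.get("mean", DEFAULT_MEAN), std=sidecar.get("std", DEFAULT_STD))
        with np.load(path.with_suffix(".npz")) as data:
            state = {k: data[k] for k in data.files}
        for name, lyr in net._named_layers():
            sub = {k[len(name) + 1:]: v for k, v in state.items() if k.startswith(name + ".")}
            current = lyr.state()
            if set(sub) != set(current) or any(
                    sub[k].shape != current[k].shape for k in current):
                raise IOError(f"checkpoint incompatible with preset "
                              f"{net.architecture!r} at layer {name}")
            lyr.load_state(sub)
        return net
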