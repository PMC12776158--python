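"""Factorized student and teacher architectures.

Both networks map a 1-channel H x W frame to a 1-channel H x W reconstruction
(magnification 1 — no net up-sampling) and are split in two at the
penultimate 32-channel representation:

* **body**: everything up to and including the 32-channel "hint" layer, the
  representation matched during hint learning;
* **head**: the final reconstruction convolution (32 -> 1).

The student is SRCNN, the classic three-layer super-resolution network
(9x9 conv to 64 channels, 1x1 conv to 32, 5x5 reconstruction).  The teacher
is a DRL-STORM-style encoder-decoder: three conv/max-pool stages down, three
up-sample/conv stages back up, with an additive skip connection carrying a
1x1-projected (and block-averaged) copy of the input to the encoder output.
Encoder/decoder widths are configurable; the defaults follow a
Deep-STORM-like progression (32, 64, 128) / (64, 32, 32).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from stormdistill.nn import (
    AvgPool,
    Conv2d,
    Layer,
    MaxPool2,
    Param,
    ReLU,
    Sequential,
    UpsampleBilinear2,
    UpsampleNearest2,
)

HINT_CHANNELS = 32


class FactorizedModel:
    """A network factorized as ``head(body(x))`` at the 32-channel hint layer."""

    def __init__(self, name: str, body: Layer, head: Layer,
                 spatial_divisor: int = 1, manifest: dict | None = None):
        self.name = name
        self.body = body
        self.head = head
        #: input H and W must be multiples of this (pooling depth constraint)
        self.spatial_divisor = spatial_divisor
        self.manifest = dict(manifest or {})

    # -- forward ----------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected a (N, 1, H, W) batch, got {x.shape}")
        d = self.spatial_divisor
        if x.shape[2] % d or x.shape[3] % d:
            raise ValueError(
                f"{self.name} requires H and W divisible by {d} "
                f"(got {x.shape[2]}x{x.shape[3]}); pad the input first"
            )
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.forward_hint(x))

    def forward_hint(self, x: np.ndarray) -> np.ndarray:
        """Body output only: the 32-channel hint representation."""
        return self.body.forward(self._check_input(x))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return self.body.backward(self.head.backward(grad_out))

    __call__ = forward

    # -- parameters -------------------------------------------------------
    def params(self) -> list[Param]:
        return self.body.params() + self.head.params()

    def trainable_params(self) -> list[Param]:
        return [p for p in self.params() if p.trainable]

    @property
    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    @property
    def head_param_count(self) -> int:
        return int(sum(p.value.size for p in self.head.params()))

    def freeze_body(self) -> "FactorizedModel":
        """Exclude every body parameter from optimization (idempotent)."""
        for p in self.body.params():
            p.trainable = False
        return self

    def freeze_all(self) -> "FactorizedModel":
        for p in self.params():
            p.trainable = False
        return self

    @property
    def body_frozen(self) -> bool:
        return all(not p.trainable for p in self.body.params())

    # -- state ------------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list does not match parameter structure")
        for p, w in zip(own, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"shape mismatch for {p.name}: {p.value.shape} vs {w.shape}")
            p.value[...] = w

    def weights_digest(self) -> str:
        """SHA-256 over all parameter bytes — used by the freezing contracts."""
        h = hashlib.sha256()
        for p in self.params():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()

    def body_digest(self) -> str:
        h = hashlib.sha256()
        for p in self.body.params():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()


def build_srcnn(rng_seed: int = 0) -> FactorizedModel:
    """The SRCNN student.

    body: 9x9 conv (1->64) + ReLU, then a 1x1 conv (64->32) + ReLU producing
    the hint representation; head: 5x5 conv (32->1).  8129 parameters total.
    """
    rng = np.random.default_rng(rng_seed)
    feat = Conv2d(1, 64, 9, rng, name="feat")
    feat.needs_input_grad = False  # first layer: no gradient flows past it
    body = Sequential(
        feat,
        ReLU(),
        Conv2d(64, HINT_CHANNELS, 1, rng, name="map"),
        ReLU(),
    )
    head = Sequential(Conv2d(HINT_CHANNELS, 1, 5, rng, name="recon"))
    manifest = {"arch": "srcnn", "rng_seed": int(rng_seed), "kernels": [9, 1, 5],
                "widths": [64, HINT_CHANNELS]}
    return FactorizedModel("srcnn", body, head, spatial_divisor=1, manifest=manifest)


class _EncoderDecoderBody(Layer):
    """Teacher body: conv/pool encoder, input skip, up-sample/conv decoder."""

    def __init__(self, enc_widths, dec_widths, skip_mode, upsample, rng):
        if dec_widths[-1] != HINT_CHANNELS:
            raise ValueError(f"decoder must end at {HINT_CHANNELS} channels")
        self.skip_mode = skip_mode
        enc = []
        in_ch = 1
        for i, w in enumerate(enc_widths):
            enc += [Conv2d(in_ch, w, 3, rng, name=f"enc{i}"), ReLU(), MaxPool2()]
            in_ch = w
        enc[0].needs_input_grad = False  # first layer: no gradient flows past it
        self.encoder = Sequential(*enc)
        bottleneck_ch = enc_widths[-1]
        self.skip_pool = AvgPool(2 ** len(enc_widths))
        self.skip_proj = Conv2d(1, bottleneck_ch, 1, rng, name="skip")
        self.skip_proj.needs_input_grad = False  # fed directly by the input
        up = UpsampleBilinear2 if upsample == "bilinear" else UpsampleNearest2
        dec = []
        in_ch = 2 * bottleneck_ch if skip_mode == "concat" else bottleneck_ch
        for i, w in enumerate(dec_widths):
            dec += [up(), Conv2d(in_ch, w, 3, rng, name=f"dec{i}"), ReLU()]
            in_ch = w
        self.decoder = Sequential(*dec)

    def params(self) -> list[Param]:
        return self.encoder.params() + self.skip_proj.params() + self.decoder.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        enc_out = self.encoder.forward(x)
        skip = self.skip_proj.forward(self.skip_pool.forward(x))
        if self.skip_mode == "concat":
            self._split = enc_out.shape[1]
            joined = np.concatenate([enc_out, skip], axis=1)
        else:
            joined = enc_out + skip
        return self.decoder.forward(joined)

    def backward(self, grad_out: np.ndarray) -> np.ndarray | None:
        g = self.decoder.backward(grad_out)
        if self.skip_mode == "concat":
            g_enc, g_skip = g[:, : self._split], g[:, self._split :]
        else:
            g_enc, g_skip = g, g
        gx = self.encoder.backward(np.ascontiguousarray(g_enc))
        g_skip_in = self.skip_proj.backward(np.ascontiguousarray(g_skip))
        if gx is None or g_skip_in is None:
            return None  # first-layer convs opted out of input grads
        return gx + self.skip_pool.backward(g_skip_in)


def build_drlstorm(
    rng_seed: int = 0,
    enc_widths: tuple[int, ...] = (32, 64, 128),
    dec_widths: tuple[int, ...] = (64, 32, HINT_CHANNELS),
    skip_mode: str = "add",
    upsample: str = "nearest",
) -> FactorizedModel:
    """The DRL-STORM-style teacher.

    Encoder: ``len(enc_widths)`` stages of [3x3 conv + ReLU, 2x2 max-pool];
    a 1x1-projected, block-averaged copy of the input joins the encoder
    output (additively by default, concatenation optional).  Decoder:
    matching stages of [2x up-sample, 3x3 conv + ReLU] ending at the
    32-channel hint layer.  Head: 3x3 conv (32->1).  Inputs must have H and W
    divisible by ``2**len(enc_widths)`` (8 for the defaults).
    """
    if skip_mode not in ("add", "concat"):
        raise ValueError("skip_mode must be 'add' or 'concat'")
    if upsample not in ("nearest", "bilinear"):
        raise ValueError("upsample must be 'nearest' or 'bilinear'")
    rng = np.random.default_rng(rng_seed)
    body = _EncoderDecoderBody(tuple(enc_widths), tuple(dec_widths), skip_mode, upsample, rng)
    head = Sequential(Conv2d(HINT_CHANNELS, 1, 3, rng, name="recon"))
    manifest = {
        "arch": "drlstorm",
        "rng_seed": int(rng_seed),
        "enc_widths": list(enc_widths),
        "dec_widths": list(dec_widths),
        "skip_mode": skip_mode,
        "upsample": upsample,
    }
    return FactorizedModel(
        "drlstorm", body, head, spatial_divisor=2 ** len(enc_widths), manifest=manifest
    )


_BUILDERS = {"srcnn": build_srcnn, "drlstorm": build_drlstorm}


def build_model(arch: str, rng_seed: int = 0, **kwargs) -> FactorizedModel:
    """Build by architecture name (``srcnn`` or ``drlstorm``)."""
    try:
        builder = _BUILDERS[arch]
    except KeyError:
        raise ValueError(f"unknown architecture {arch!r}; expected one of {sorted(_BUILDERS)}")
    return builder(rng_seed=rng_seed, **kwargs)


def save_checkpoint(model: FactorizedModel, path: str | Path) -> Path:
    """Weights blob (flat .npy, byte-deterministic) + diffable JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    weights = model.get_weights()
    flat = np.concatenate([w.ravel() for w in weights]).astype(np.float32)
    np.save(path / "weights.npy", flat)
    manifest = dict(model.manifest)
    manifest.update({"name": model.name, "hint_channels": HINT_CHANNELS,
                     "param_shapes": [list(w.shape) for w in weights],
                     "weights_digest": model.weights_digest()})
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def load_checkpoint(path: str | Path) -> FactorizedModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    arch = manifest["arch"]
    kwargs = {}
    if arch == "drlstorm":
        kwargs = dict(
            enc_widths=tuple(manifest["enc_widths"]),
            dec_widths=tuple(manifest["dec_widths"]),
            skip_mode=manifest["skip_mode"],
            upsample=manifest["upsample"],
        )
    model = build_model(arch, rng_seed=manifest["rng_seed"], **kwargs)
    flat = np.load(path / "weights.npy")
    shapes = [tuple(s) for s in manifest["param_shapes"]]
    sizes = [int(np.prod(s)) for s in shapes]
    if flat.size != sum(sizes):
        raise ValueError(f"weight blob size {flat.size} does not match manifest shapes")
    weights, offset = [], 0
    for shape, size in zip(shapes, sizes):
        weights.append(flat[offset : offset + size].reshape(shape))
        offset += size
    model.set_weights(weights)
    return model
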