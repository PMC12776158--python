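"""Synthetic STORM frame simulation and patch dataset construction.

Emulates a ThunderSTORM-style generation protocol: emitters are scattered
uniformly over a physical field at a requested density (emitters per square
micrometer), blurred by a Gaussian point-spread function, summed with a
uniform fluorescent background and corrupted by Poisson shot noise to give
the diffraction-limited camera frame X.  The super-resolved ground truth Y
lives on the *same* pixel grid (magnification 1): a sparse spike image with
each emitter's photon count deposited at its nearest pixel.

Random 200x200 (configurable) patches are cropped from the X,Y pairs,
assigned to train/validation/test splits by independent categorical draws,
and the X patches are z-scored with the mean and standard deviation pooled
over the whole dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

SPLITS = ("train", "val", "test")

#: ThunderSTORM ground-truth export header
_CSV_COLUMNS = ["id", "frame", "x [nm]", "y [nm]", "intensity [photon]"]


class DatasetParseError(ValueError):
    """A persisted dataset bundle could not be read back."""


@dataclass(frozen=True)
class EmitterField:
    """Ground-truth emitter positions and photon counts on a physical grid.

    Positions are in pixel units (continuous, ``0 <= x < width_px``);
    ``pixel_size_um`` converts between the pixel grid and physical area so
    that densities are always expressed per square micrometer.
    """

    width_px: int
    height_px: int
    pixel_size_um: float
    emitters: np.ndarray  # (n, 3): x_px, y_px, photons

    def __post_init__(self):
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("field dimensions must be >= 1 pixel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        em = np.asarray(self.emitters, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "emitters", em)
        if em.size:
            x, y, p = em[:, 0], em[:, 1], em[:, 2]
            if (x < 0).any() or (x >= self.width_px).any() or (y < 0).any() or (y >= self.height_px).any():
                raise ValueError("emitter positions must lie inside the field")
            if (p <= 0).any():
                raise ValueError("emitter photon counts must be positive")

    @property
    def n_emitters(self) -> int:
        return self.emitters.shape[0]

    @property
    def area_um2(self) -> float:
        return self.width_px * self.height_px * self.pixel_size_um**2

    @property
    def density_per_um2(self) -> float:
        return self.n_emitters / self.area_um2

    def __eq__(self, other) -> bool:
        if not isinstance(other, EmitterField):
            return NotImplemented
        return (
            self.width_px == other.width_px
            and self.height_px == other.height_px
            and self.pixel_size_um == other.pixel_size_um
            and self.emitters.shape == other.emitters.shape
            and np.array_equal(self.emitters, other.emitters)
        )


@dataclass(frozen=True)
class ImagePair:
    """Diffraction-limited input ``x_dl`` and same-grid spike truth ``y_gt``."""

    x_dl: np.ndarray
    y_gt: np.ndarray
    field: EmitterField | None = None

    def __post_init__(self):
        x = np.asarray(self.x_dl, dtype=np.float64)
        y = np.asarray(self.y_gt, dtype=np.float64)
        if x.shape != y.shape:
            raise ValueError("x_dl and y_gt must share one pixel grid (magnification 1)")
        if (x < 0).any() or (y < 0).any():
            raise ValueError("images must be nonnegative")
        object.__setattr__(self, "x_dl", x)
        object.__setattr__(self, "y_gt", y)


@dataclass
class PatchDataset:
    """Paired X,Y patches with split labels and pooled normalization stats.

    ``x`` and ``y`` are ``(n, patch, patch)`` float32 stacks; ``labels`` holds
    one of ``train``/``val``/``test`` per patch.  ``norm_mean``/``norm_std``
    are ``None`` until :func:`normalize_dataset` has been applied, after which
    they record the pooled statistics needed to normalize new data at
    inference time.
    """

    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray
    patch_size: int
    rng_seed: int
    norm_mean: float | None = None
    norm_std: float | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype="U5")
        if self.x.shape != self.y.shape:
            raise ValueError("x and y patch stacks must have identical shapes")
        if self.x.ndim != 3 or (self.x.size and self.x.shape[1:] != (self.patch_size, self.patch_size)):
            raise ValueError(f"patches must be {self.patch_size}x{self.patch_size}")
        if self.labels.shape[0] != self.x.shape[0]:
            raise ValueError("one split label per patch required")
        if self.norm_std is not None and self.norm_std <= 0:
            raise ValueError("norm_std must be positive")

    def __len__(self) -> int:
        return self.x.shape[0]

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return the (x, y) patch stacks belonging to one split."""
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}; expected one of {SPLITS}")
        mask = self.labels == name
        return self.x[mask], self.y[mask]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PatchDataset):
            return NotImplemented
        return (
            np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.labels, other.labels)
            and self.patch_size == other.patch_size
            and self.rng_seed == other.rng_seed
            and self.norm_mean == other.norm_mean
            and self.norm_std == other.norm_std
        )


# ---------------------------------------------------------------------------
# generation


def simulate_emitter_field(
    width_px: int,
    height_px: int,
    pixel_size_um: float = 0.1,
    density_per_um2: float = 13.0,
    photon_model: str | tuple = "fixed",
    photons: float = 1000.0,
    rng_seed: int = 0,
) -> EmitterField:
    """Scatter emitters uniformly over a field at a Poisson-distributed count.

    The number of emitters is Poisson with mean ``density * area`` where the
    area is ``width_px * height_px * pixel_size_um**2``; positions are uniform
    over the field.  ``photon_model`` is ``"fixed"`` (every emitter emits
    ``photons``) or ``"lognormal"`` (median ``photons``, shape 0.5), matching
    the broad brightness spread of real fluorophores.
    """
    if density_per_um2 < 0:
        raise ValueError("density_per_um2 must be nonnegative")
    if width_px < 1 or height_px < 1:
        raise ValueError("field dimensions must be >= 1 pixel")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    rng = np.random.default_rng(rng_seed)
    area = width_px * height_px * pixel_size_um**2
    n = rng.poisson(density_per_um2 * area)
    x = rng.uniform(0, width_px, size=n)
    y = rng.uniform(0, height_px, size=n)
    if photon_model == "fixed":
        p = np.full(n, float(photons))
    elif photon_model == "lognormal":
        p = photons * rng.lognormal(mean=0.0, sigma=0.5, size=n)
    else:
        raise ValueError(f"unknown photon_model {photon_model!r}")
    return EmitterField(width_px, height_px, pixel_size_um, np.column_stack([x, y, p]))


def spike_image(field: EmitterField) -> np.ndarray:
    """Deposit each emitter's photons at its nearest pixel (same-grid truth)."""
    img = np.zeros((field.height_px, field.width_px))
    if field.n_emitters:
        # positions are continuous in [0, size); the containing pixel is floor
        ix = np.minimum(field.emitters[:, 0].astype(int), field.width_px - 1)
        iy = np.minimum(field.emitters[:, 1].astype(int), field.height_px - 1)
        np.add.at(img, (iy, ix), field.emitters[:, 2])
    return img


def render_pair(
    field: EmitterField,
    psf_sigma_px: float = 1.6,
    background_level: float = 200.0,
    noise_model: str = "poisson",
    rng_seed: int = 0,
) -> ImagePair:
    """Render the diffraction-limited frame and its spike ground truth.

    The clean frame is the spike image convolved with an isotropic 2-D
    Gaussian PSF of width ``psf_sigma_px`` plus a uniform background of mean
    ``background_level`` counts; ``noise_model="poisson"`` applies shot noise
    to the whole clean frame, ``"none"`` returns it noise-free (used by the
    oracle tests).
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    if background_level < 0:
        raise ValueError("background_level must be nonnegative")
    y_gt = spike_image(field)
    clean = gaussian_filter(y_gt, sigma=psf_sigma_px, mode="constant") + background_level
    if noise_model == "poisson":
        rng = np.random.default_rng(rng_seed)
        x_dl = rng.poisson(clean).astype(float)
    elif noise_model == "none":
        x_dl = clean
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    return ImagePair(x_dl=x_dl, y_gt=y_gt, field=field)


def build_patch_dataset(
    pairs: list[ImagePair],
    patch_size: int = 200,
    patches_per_image: int = 200,
    split_probs: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng_seed: int = 0,
) -> PatchDataset:
    """Crop random paired patches and assign each to a split by a random draw.

    Offsets are uniform (patches may overlap) and identical for X and Y;
    every patch is labeled train/val/test independently with ``split_probs``.
    """
    probs = np.asarray(split_probs, dtype=float)
    if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("split_probs must be three probabilities summing to 1")
    if patches_per_image < 0:
        raise ValueError("patches_per_image must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    xs, ys, labels = [], [], []
    for pair in pairs:
        h, w = pair.x_dl.shape
        if patch_size > min(h, w):
            raise ValueError(f"patch_size {patch_size} exceeds image dimensions {h}x{w}")
        for _ in range(patches_per_image):
            r = rng.integers(0, h - patch_size + 1)
            c = rng.integers(0, w - patch_size + 1)
            xs.append(pair.x_dl[r : r + patch_size, c : c + patch_size])
            ys.append(pair.y_gt[r : r + patch_size, c : c + patch_size])
            labels.append(SPLITS[rng.choice(3, p=probs)])
    n = len(xs)
    shape = (n, patch_size, patch_size)
    return PatchDataset(
        x=np.asarray(xs, dtype=np.float32).reshape(shape),
        y=np.asarray(ys, dtype=np.float32).reshape(shape),
        labels=np.asarray(labels),
        patch_size=patch_size,
        rng_seed=int(rng_seed),
    )


def normalize_dataset(dataset: PatchDataset) -> PatchDataset:
    """Z-score the X patches with mean/std pooled over the entire dataset.

    Ground-truth Y patches are left untouched; the pooled statistics are
    stored on the returned dataset for inference-time reuse.
    """
    if len(dataset) == 0:
        raise ValueError("cannot normalize an empty dataset")
    mean = float(dataset.x.mean(dtype=np.float64))
    std = float(dataset.x.std(dtype=np.float64))
    if std == 0:
        raise ValueError("pooled standard deviation is zero (constant dataset)")
    x = ((dataset.x.astype(np.float64) - mean) / std).astype(np.float32)
    return PatchDataset(
        x=x,
        y=dataset.y.copy(),
        labels=dataset.labels.copy(),
        patch_size=dataset.patch_size,
        rng_seed=dataset.rng_seed,
        norm_mean=mean,
        norm_std=std,
        meta=dict(dataset.meta),
    )


def make_dataset(
    n_images: int = 5,
    image_size: int = 1000,
    pixel_size_um: float = 0.1,
    density_per_um2: float = 13.0,
    background_level: float = 200.0,
    psf_sigma_px: float = 1.6,
    patch_size: int = 200,
    patches_per_image: int = 200,
    split_probs: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng_seed: int = 0,
    photon_model: str = "fixed",
    photons: float = 1000.0,
    y_scale: str = "unit",
) -> PatchDataset:
    """One-call study-protocol dataset: simulate, render, patch, normalize.

    Defaults reproduce the dense-emitter protocol (five 1000x1000 frames at
    13 emitters/um^2, background 200, 200 random 200x200 patches per frame,
    ~80:10:10 split); every argument is configurable for scaled-down runs.

    ``y_scale="unit"`` divides the spike targets by the nominal photon count
    so a single emitter deposits ~1.0 — the amplitude convention under which
    the sparse-reconstruction losses operate at O(1) magnitudes;
    ``"photons"`` keeps raw photon counts.  The choice is recorded in
    ``meta['y_scale']``.
    """
    rng = np.random.default_rng(rng_seed)
    pairs = []
    for _ in range(n_images):
        field = simulate_emitter_field(
            image_size,
            image_size,
            pixel_size_um,
            density_per_um2,
            photon_model=photon_model,
            photons=photons,
            rng_seed=int(rng.integers(2**31)),
        )
        pairs.append(
            render_pair(
                field,
                psf_sigma_px=psf_sigma_px,
                background_level=background_level,
                rng_seed=int(rng.integers(2**31)),
            )
        )
    ds = build_patch_dataset(
        pairs, patch_size, patches_per_image, split_probs, rng_seed=int(rng.integers(2**31))
    )
    if y_scale == "unit":
        ds.y = ds.y / np.float32(photons)
    elif y_scale != "photons":
        raise ValueError(f"unknown y_scale {y_scale!r}")
    ds.meta.update(
        dict(
            n_images=n_images,
            image_size=image_size,
            pixel_size_um=pixel_size_um,
            density_per_um2=density_per_um2,
            background_level=background_level,
            psf_sigma_px=psf_sigma_px,
            patches_per_image=patches_per_image,
            split_probs=list(split_probs),
            photon_model=photon_model,
            photons=photons,
            y_scale=y_scale,
        )
    )
    return normalize_dataset(ds)


# ---------------------------------------------------------------------------
# persistence


def write_dataset(dataset: PatchDataset, path: str | Path) -> Path:
    """Persist a dataset bundle: per-array ``.npy`` files plus a JSON sidecar.

    Plain ``.npy`` records are byte-deterministic (no archive timestamps), so
    a rerun of the same generation config yields identical artifact hashes.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "x.npy", dataset.x)
    np.save(path / "y.npy", dataset.y)
    np.save(path / "labels.npy", dataset.labels)
    sidecar = {
        "patch_size": dataset.patch_size,
        "rng_seed": dataset.rng_seed,
        "norm_mean": dataset.norm_mean,
        "norm_std": dataset.norm_std,
        "meta": dataset.meta,
    }
    (path / "meta.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_dataset(path: str | Path) -> PatchDataset:
    """Read a dataset bundle written by :func:`write_dataset` (bit-exact)."""
    path = Path(path)
    meta_path = path / "meta.json"
    records = [path / "x.npy", path / "y.npy", path / "labels.npy", meta_path]
    for p in records:
        if not p.exists():
            raise DatasetParseError(f"missing dataset record: {p}")
    arrays = {}
    for p in records[:3]:
        try:
            arrays[p.stem] = np.load(p)
        except Exception as exc:
            raise DatasetParseError(f"unreadable patch record {p}: {exc}") from exc
    x, y, labels = arrays["x"], arrays["y"], arrays["labels"]
    try:
        sidecar = json.loads(meta_path.read_text())
    except Exception as exc:
        raise DatasetParseError(f"unreadable sidecar {meta_path}: {exc}") from exc
    return PatchDataset(
        x=x,
        y=y,
        labels=labels,
        patch_size=int(sidecar["patch_size"]),
        rng_seed=int(sidecar["rng_seed"]),
        norm_mean=sidecar["norm_mean"],
        norm_std=sidecar["norm_std"],
        meta=sidecar.get("meta", {}),
    )


def write_emitters_csv(field: EmitterField, path: str | Path) -> Path:
    """Export the ground-truth emitter list as a ThunderSTORM-style CSV."""
    path = Path(path)
    nm = field.pixel_size_um * 1000.0
    df = pd.DataFrame(
        {
            "id": np.arange(1, field.n_emitters + 1),
            "frame": np.ones(field.n_emitters, dtype=int),
            "x [nm]": field.emitters[:, 0] * nm,
            "y [nm]": field.emitters[:, 1] * nm,
            "intensity [photon]": field.emitters[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_emitters_csv(
    path: str | Path, width_px: int, height_px: int, pixel_size_um: float
) -> EmitterField:
    """Re-import a ThunderSTORM-style CSV onto a pixel grid."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetParseError(f"emitter CSV {path} lacks columns {missing}")
    nm = pixel_size_um * 1000.0
    em = np.column_stack(
        [df["x [nm]"] / nm, df["y [nm]"] / nm, df["intensity [photon]"]]
    )
    return EmitterField(width_px, height_px, pixel_size_um, em)
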