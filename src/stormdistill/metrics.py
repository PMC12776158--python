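"""Evaluation metrics: NMSE, SSIM, per-patch reports, cross-profiles.

NMSE follows the convention used in this study's evaluation,
``||pred - truth||^2 / ||truth||`` — note the *unsquared* denominator, which
makes the quantity scale linearly when both images are scaled together.  A
``standard`` mode dividing by ``||truth||^2`` is available.  Values are
stored as fractions; multiply by 100 to render percentages.

SSIM is the standard windowed structural similarity with stabilizers
C1 = (0.01 R)^2, C2 = (0.03 R)^2 for data range R, a uniform (default) or
Gaussian-weighted window, unbiased local covariances, and the mean taken
over fully valid windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, uniform_filter

from stormdistill.simulate import PatchDataset


@dataclass
class MetricsReport:
    """Per-patch NMSE/SSIM vectors with summary statistics."""

    nmse: np.ndarray
    ssim: np.ndarray
    model_name: str
    dataset_id: str

    def __post_init__(self):
        self.nmse = np.asarray(self.nmse, dtype=float)
        self.ssim = np.asarray(self.ssim, dtype=float)
        if self.nmse.shape != self.ssim.shape:
            raise ValueError("metric vectors must have one entry per patch")

    @property
    def summary(self) -> dict:
        out = {}
        for name, v in (("nmse", self.nmse), ("ssim", self.ssim)):
            out[name] = {
                "mean": float(v.mean()),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
        return out


def nmse(pred: np.ndarray, truth: np.ndarray, mode: str = "printed") -> float:
    """Normalized mean square error between two images.

    ``printed`` divides the squared error by ``||truth||_2`` (this study's
    convention); ``standard`` divides by ``||truth||_2^2``.
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tn = np.sqrt((t**2).sum())
    if tn == 0:
        raise ValueError("truth image has zero norm; NMSE undefined")
    err = ((p - t) ** 2).sum()
    if mode == "printed":
        return float(err / tn)
    if mode == "standard":
        return float(err / tn**2)
    raise ValueError(f"unknown NMSE mode {mode!r}")


def ssim(
    pred: np.ndarray,
    truth: np.ndarray,
    window: int = 7,
    data_range: float | None = None,
    gaussian_window: bool = False,
    sigma: float = 1.5,
) -> float:
    """Windowed structural similarity index in [-1, 1].

    ``data_range`` defaults to ``truth.max() - truth.min()``; the local means
    and (unbiased) covariances use a ``window`` x ``window`` uniform filter,
    or a Gaussian-weighted window of width ``sigma`` when
    ``gaussian_window=True``, and the SSIM map is averaged over windows fully
    inside the image.
    """
    a = np.asarray(pred, dtype=np.float64)
    b = np.asarray(truth, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("pred and truth must be 2-D images of one shape")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(a.shape):
        raise ValueError(f"window {window} exceeds image dims {a.shape}")
    if data_range is None:
        data_range = float(b.max() - b.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive (constant truth needs an override)")

    if gaussian_window:
        truncate = (window - 1) / 2 / sigma  # filter support = requested window
        def filt(img):
            return gaussian_filter(img, sigma, truncate=truncate)
        cov_norm = 1.0
    else:
        def filt(img):
            return uniform_filter(img, size=window)
        npix = window**2
        cov_norm = npix / (npix - 1)

    ux, uy = filt(a), filt(b)
    vx = cov_norm * (filt(a * a) - ux * ux)
    vy = cov_norm * (filt(b * b) - uy * uy)
    vxy = cov_norm * (filt(a * b) - ux * uy)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    smap = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (window - 1) // 2
    return float(smap[pad:-pad, pad:-pad].mean())


def evaluate(
    model,
    dataset: PatchDataset,
    split: str = "test",
    nmse_mode: str = "printed",
    ssim_window: int = 7,
    batch_size: int = 16,
) -> MetricsReport:
    """Per-patch NMSE and SSIM of a model's outputs against the spike truth.

    ``dataset`` must carry its pooled normalization stats (inputs are
    already z-scored by them); ``model`` is anything exposing
    ``forward((n,1,H,W)) -> (n,1,H,W)``.  Deterministic for a fixed
    checkpoint, split and config.
    """
    if dataset.norm_std is None:
        raise ValueError("dataset lacks normalization stats; run normalize_dataset first")
    x, y = dataset.split(split)
    if x.shape[0] == 0:
        raise ValueError(f"split {split!r} is empty")
    nmses, ssims = [], []
    for i in range(0, x.shape[0], batch_size):
        xb = x[i : i + batch_size][:, None].astype(np.float32)
        pred = np.asarray(model.forward(xb))[:, 0]
        for j in range(pred.shape[0]):
            t = y[i + j]
            nmses.append(nmse(pred[j], t, mode=nmse_mode))
            ssims.append(ssim(pred[j], t, window=ssim_window))
    name = getattr(model, "name", type(model).__name__)
    ds_id = f"{dataset.rng_seed}/{split}/n={len(nmses)}"
    return MetricsReport(nmse=np.array(nmses), ssim=np.array(ssims),
                         model_name=name, dataset_id=ds_id)


def cross_profile(
    image: np.ndarray,
    start_px: tuple[float, float],
    end_px: tuple[float, float],
    n_samples: int = 100,
) -> np.ndarray:
    """Bilinearly interpolated intensities along a line segment.

    ``start_px``/``end_px`` are (row, col) endpoints, both inside the image;
    returns ``n_samples`` evenly spaced values from start to end inclusive.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("cross_profile expects a 2-D image")
    for pt in (start_px, end_px):
        r, c = pt
        if not (0 <= r <= img.shape[0] - 1 and 0 <= c <= img.shape[1] - 1):
            raise ValueError(f"endpoint {pt} lies outside the image {img.shape}")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rows = np.linspace(start_px[0], end_px[0], n_samples)
    cols = np.linspace(start_px[1], end_px[1], n_samples)
    return map_coordinates(img, [rows, cols], order=1, mode="nearest")
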