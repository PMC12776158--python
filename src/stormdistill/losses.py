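"""Reconstruction and distillation losses.

Three losses drive the study:

* **L1L2** — the sparse-reconstruction loss used throughout DL-based SMLM:
  squared error between Gaussian-blurred prediction and Gaussian-blurred
  spike target (the 3x3 blur grants sub-pixel tolerance around each spike),
  plus an L1 penalty on the prediction, weighted by the sparsity
  hyperparameter lambda (with the lambda/2 convention on the squared term):

      L(x, xhat) = (1/N) sum_i [ (lam/2) ||xhat_i*g - x_i*g||^2 + ||xhat_i||_1 ]

* **Attentive Imitation Loss (AIL)** — blends the student's own L1L2 against
  the ground truth (weight alpha) with a teacher-informed term scaled by Phi,
  a normalization built from the teacher's per-sample training errors e_T
  and their range eta = max(e_T) - min(e_T).  Two forms of the teacher term
  are supported: ``as_printed`` penalizes the teacher-vs-truth squared error
  (with the student's L1), and ``imitation`` penalizes the student-vs-teacher
  squared error, the form standard in the regression-distillation literature.
  Only the latter gives the teacher term a student gradient beyond the L1.

* **hint MSE** — mean squared error between the student's and teacher's
  32-channel hint representations, used for hint learning.

Every loss has a companion ``*_grad`` returning the exact gradient with
respect to the student prediction, which is what the training loop
backpropagates through the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from stormdistill.models import HINT_CHANNELS


class DegenerateNormalizationError(ValueError):
    """Raised when eta = max(e_T) - min(e_T) is zero and Phi is undefined."""


@dataclass(frozen=True)
class GaussianKernel:
    """A normalized, flip-symmetric discretized Gaussian (default 3x3, sigma 1)."""

    size: int
    sigma: float
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (self.size, self.size):
            raise ValueError("kernel weights must be size x size")
        object.__setattr__(self, "weights", w)


def make_gaussian_kernel(size: int = 3, sigma: float = 1.0) -> GaussianKernel:
    """Sample an isotropic Gaussian at integer offsets and normalize to sum 1."""
    if size % 2 == 0 or size < 1:
        raise ValueError(f"kernel size must be odd and >= 1, got {size}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.arange(size) - size // 2
    g1 = np.exp(-(r**2) / (2.0 * sigma**2))
    w = np.outer(g1, g1)
    return GaussianKernel(size=size, sigma=sigma, weights=w / w.sum())


DEFAULT_KERNEL = make_gaussian_kernel(3, 1.0)


def _as3d(batch: np.ndarray) -> np.ndarray:
    """Accept (N,H,W) or (N,1,H,W) batches; return (N,H,W) float64."""
    b = np.asarray(batch, dtype=np.float64)
    if b.ndim == 4:
        if b.shape[1] != 1:
            raise ValueError(f"expected single-channel images, got {b.shape}")
        b = b[:, 0]
    if b.ndim != 3:
        raise ValueError(f"expected a batch of 2-D images, got shape {batch.shape}")
    return b


def blur(batch: np.ndarray, kernel: GaussianKernel = DEFAULT_KERNEL) -> np.ndarray:
    """Zero-padded same-size convolution of each image with the kernel."""
    b = _as3d(batch)
    pad = kernel.size // 2
    bp = np.pad(b, ((0, 0), (pad, pad), (pad, pad)))
    cols = sliding_window_view(bp, (kernel.size, kernel.size), axis=(1, 2))
    # kernel is flip-symmetric, so correlation equals convolution
    return np.tensordot(cols, kernel.weights, axes=([3, 4], [0, 1]))


def per_sample_l1l2(
    pred: np.ndarray, truth: np.ndarray, lam: float, kernel: GaussianKernel = DEFAULT_KERNEL
) -> np.ndarray:
    """Vector of per-sample L1L2 losses (the batch loss without the 1/N mean)."""
    p, t = _as3d(pred), _as3d(truth)
    if p.shape != t.shape:
        raise ValueError(f"prediction {p.shape} and truth {t.shape} shapes differ")
    if p.shape[0] < 1:
        raise ValueError("batch must contain at least one sample")
    diff = blur(p - t, kernel)
    sq = (diff**2).sum(axis=(1, 2))
    l1 = np.abs(p).sum(axis=(1, 2))
    return (lam / 2.0) * sq + l1


def l1l2_loss(
    pred: np.ndarray, truth: np.ndarray, lam: float, kernel: GaussianKernel = DEFAULT_KERNEL
) -> float:
    """Batch-mean L1L2 loss."""
    return float(per_sample_l1l2(pred, truth, lam, kernel).mean())


def l1l2_grad(
    pred: np.ndarray, truth: np.ndarray, lam: float, kernel: GaussianKernel = DEFAULT_KERNEL
) -> np.ndarray:
    """d l1l2_loss / d pred, shape (N,H,W).

    The squared term differentiates to lam * g*(g*(pred-truth)) (the kernel
    is symmetric so the adjoint blur is the blur itself); the L1 term
    contributes sign(pred), with subgradient 0 at exact zeros.
    """
    p, t = _as3d(pred), _as3d(truth)
    n = p.shape[0]
    g = lam * blur(blur(p - t, kernel), kernel) + np.sign(p)
    return g / n


def teacher_error_vector(
    teacher_pred: np.ndarray,
    truth: np.ndarray,
    lam: float,
    kernel: GaussianKernel = DEFAULT_KERNEL,
    batch_size: int = 64,
) -> np.ndarray:
    """Per-sample L1L2 losses of the frozen trained teacher over a dataset.

    One entry per training sample; both the L1 and squared terms are taken on
    the teacher's own predictions (the teacher's error vector exists before
    any student does).
    """
    p, t = _as3d(teacher_pred), _as3d(truth)
    if p.shape != t.shape:
        raise ValueError("teacher predictions and truths must align")
    if p.shape[0] == 0:
        raise ValueError("teacher error vector needs at least one sample")
    out = [
        per_sample_l1l2(p[i : i + batch_size], t[i : i + batch_size], lam, kernel)
        for i in range(0, p.shape[0], batch_size)
    ]
    return np.concatenate(out)


def compute_eta_phi(e_T: np.ndarray) -> tuple[float, float]:
    """eta = max(e_T) - min(e_T); Phi = mean(e_T) / eta."""
    e = np.asarray(e_T, dtype=np.float64).ravel()
    if e.size < 2:
        raise ValueError("e_T must contain at least two entries")
    eta = float(e.max() - e.min())
    if eta <= 0:
        raise DegenerateNormalizationError(
            "e_T is constant (eta = 0); Phi is undefined"
        )
    return eta, float(e.mean() / eta)


@dataclass
class AILContext:
    """Everything the attentive imitation loss needs.

    lam and alpha are the sparsity and attention weights; ``e_T`` holds the
    frozen teacher's per-sample L1L2 losses over the training set, from which
    eta (their range) and Phi (their mean over eta) are derived.  ``mode``
    selects the teacher term: ``as_printed`` (teacher-vs-truth) or
    ``imitation`` (student-vs-teacher).
    """

    lam: float
    alpha: float
    e_T: np.ndarray
    eta: float
    phi: float
    kernel: GaussianKernel = field(default_factory=lambda: DEFAULT_KERNEL)
    mode: str = "as_printed"

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.mode not in ("as_printed", "imitation"):
            raise ValueError(f"unknown AIL mode {self.mode!r}")
        if self.eta <= 0:
            raise DegenerateNormalizationError("eta must be positive")

    @classmethod
    def from_teacher_errors(
        cls,
        e_T: np.ndarray,
        lam: float,
        alpha: float,
        kernel: GaussianKernel = DEFAULT_KERNEL,
        mode: str = "as_printed",
    ) -> "AILContext":
        eta, phi = compute_eta_phi(e_T)
        return cls(lam=lam, alpha=alpha, e_T=np.asarray(e_T, dtype=np.float64),
                   eta=eta, phi=phi, kernel=kernel, mode=mode)

    def with_alpha(self, alpha: float) -> "AILContext":
        return AILContext(lam=self.lam, alpha=alpha, e_T=self.e_T, eta=self.eta,
                          phi=self.phi, kernel=self.kernel, mode=self.mode)


def ail_loss(
    student_pred: np.ndarray,
    teacher_pred: np.ndarray,
    truth: np.ndarray,
    ctx: AILContext,
) -> float:
    """Attentive imitation loss over a batch.

    alpha = 1 reduces exactly to the student's plain L1L2 loss (the code
    takes that branch literally so the reduction is bit-exact).
    """
    if ctx.alpha == 1.0:
        return l1l2_loss(student_pred, truth, ctx.lam, ctx.kernel)
    s, t, x = _as3d(student_pred), _as3d(teacher_pred), _as3d(truth)
    if not (s.shape == t.shape == x.shape):
        raise ValueError("student, teacher and truth batches must share a shape")
    own = per_sample_l1l2(s, x, ctx.lam, ctx.kernel)
    l1_s = np.abs(s).sum(axis=(1, 2))
    if ctx.mode == "as_printed":
        sq = (blur(t - x, ctx.kernel) ** 2).sum(axis=(1, 2))
    else:  # imitation
        sq = (blur(s - t, ctx.kernel) ** 2).sum(axis=(1, 2))
    teacher_term = (ctx.lam / 2.0) * sq + l1_s
    per = ctx.alpha * own + (1.0 - ctx.alpha) * ctx.phi * teacher_term
    return float(per.mean())


def ail_grad(
    student_pred: np.ndarray,
    teacher_pred: np.ndarray,
    truth: np.ndarray,
    ctx: AILContext,
) -> np.ndarray:
    """d ail_loss / d student_pred, shape (N,H,W)."""
    if ctx.alpha == 1.0:
        return l1l2_grad(student_pred, truth, ctx.lam, ctx.kernel)
    s, t, x = _as3d(student_pred), _as3d(teacher_pred), _as3d(truth)
    n = s.shape[0]
    g = ctx.alpha * (ctx.lam * blur(blur(s - x, ctx.kernel), ctx.kernel) + np.sign(s))
    if ctx.mode == "as_printed":
        # teacher-vs-truth squared term carries no student gradient
        g += (1.0 - ctx.alpha) * ctx.phi * np.sign(s)
    else:
        g += (1.0 - ctx.alpha) * ctx.phi * (
            ctx.lam * blur(blur(s - t, ctx.kernel), ctx.kernel) + np.sign(s)
        )
    return g / n


def _check_hint_shapes(student_features: np.ndarray, teacher_features: np.ndarray) -> None:
    s, t = student_features, teacher_features
    if s.ndim != 4 or t.ndim != 4:
        raise ValueError("hint features must be (N, C, H, W) batches")
    if s.shape[1] != t.shape[1]:
        raise ValueError(
            f"hint channel counts differ ({s.shape[1]} vs {t.shape[1]}); "
            f"both models must expose the {HINT_CHANNELS}-channel hint layer"
        )
    if s.shape != t.shape:
        raise ValueError(f"hint feature shapes differ: {s.shape} vs {t.shape}")


def hint_loss(
    student_features: np.ndarray, teacher_features: np.ndarray, reduction: str = "mean"
) -> float:
    """MSE between student and teacher hint representations.

    ``mean`` averages over every element so the value is resolution
    independent; ``sum`` accumulates instead.
    """
    _check_hint_shapes(student_features, teacher_features)
    d = np.asarray(student_features, dtype=np.float64) - np.asarray(
        teacher_features, dtype=np.float64
    )
    if reduction == "mean":
        return float((d**2).mean())
    if reduction == "sum":
        return float((d**2).sum())
    raise ValueError(f"unknown reduction {reduction!r}")


def hint_grad(
    student_features: np.ndarray, teacher_features: np.ndarray, reduction: str = "mean"
) -> np.ndarray:
    """d hint_loss / d student_features."""
    _check_hint_shapes(student_features, teacher_features)
    d = np.asarray(student_features, dtype=np.float64) - np.asarray(
        teacher_features, dtype=np.float64
    )
    if reduction == "mean":
        return 2.0 * d / d.size
    if reduction == "sum":
        return 2.0 * d
    raise ValueError(f"unknown reduction {reduction!r}")
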