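"""Heatmap machinery: DSNT coordinate extraction, target splotches, Wing
loss, Jensen-Shannon regularisation and the combined training objective.

The DSNT (differentiable spatial-to-numerical transform) reads a softmax-
normalised heatmap as a probability distribution over a fixed coordinate
grid and returns the expected coordinate.  With 1-based indices the grid is

    X_j = (2j - W - 1) / W,   Y_i = (2i - H - 1) / H,

so every coordinate lies strictly inside (-1, 1) and the grid is symmetric
about zero.  Normalised coordinates are resolution-agnostic: the same
position maps to (almost) the same value at heatmap and input resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class WingParams:
    """Wing loss hyperparameters: ``w`` confines the non-linear range to
    (-w, w); ``epsilon`` limits the curvature of the log region."""

    w: float = 10.0
    epsilon: float = 2.0

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.epsilon > 0):
            raise ValueError(f"WingParams must be positive, got {self}")


@dataclass(frozen=True)
class TargetHeatmapSpec:
    """Shape of the stage-2 regularisation splotch."""

    kind: str = "gaussian"  # {"gaussian", "exponential", "none"}
    sigma: float = 6.9

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "exponential", "none"):
            raise ValueError(f"unknown heatmap kind {self.kind!r}")
        if self.kind != "none" and not (self.sigma > 0):
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class HeatmapStack:
    """Per-landmark 2-D score grids for one network stage (K x H x W)."""

    values: np.ndarray
    stage: int

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("expected (n_landmarks, H, W) scores")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite heatmap scores")
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")

    def probabilities(self) -> np.ndarray:
        return np.stack([softmax2d(v) for v in self.values])


def make_coord_grids(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """The DSNT coordinate vectors ``(X, Y)`` with X_j = (2j - W - 1)/W."""
    if h < 1 or w < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {h}x{w}")
    j = np.arange(1, w + 1, dtype=float)
    i = np.arange(1, h + 1, dtype=float)
    return (2 * j - w - 1) / w, (2 * i - h - 1) / h


def softmax2d(scores: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over all cells of a 2-D grid."""
    z = np.exp(scores - scores.max())
    return z / z.sum()


def dsnt(heatmap: np.ndarray) -> tuple[float, float]:
    """Expected (x, y) in (-1, 1)^2 of the softmax of a score grid.

    Uses compensated summation so symmetric grids land exactly on zero
    (the coordinate axes are exact float negations about the centre).
    """
    p = softmax2d(np.asarray(heatmap, dtype=float))
    h, w = p.shape
    xg, yg = make_coord_grids(h, w)
    return float(math.fsum(p.sum(axis=0) * xg)), float(math.fsum(p.sum(axis=1) * yg))


def normalized_to_pixel(x: float, n: int) -> float:
    """Map a normalised coordinate to a 0-based pixel index on an n-cell
    axis (inverse of the DSNT grid rule, continuous)."""
    return (x * n + n + 1) / 2.0 - 1.0


def pixel_to_normalized(c: float, n: int) -> float:
    """Map a 0-based pixel index on an n-cell axis into the DSNT frame."""
    return (2.0 * (c + 1.0) - n - 1.0) / n


def wing_loss(x: np.ndarray | float, params: WingParams = WingParams()) -> np.ndarray | float:
    """Wing loss: w*ln(1 + |x|/eps) inside (-w, w), linear with matched
    offset outside.  Even, continuous, monotone in |x|."""
    ax = np.abs(np.asarray(x, dtype=float))
    w, eps = params.w, params.epsilon
    c = w - w * math.log(1.0 + w / eps)
    out = np.where(ax < w, w * np.log1p(ax / eps), ax - c)
    return float(out) if np.isscalar(x) else out


def target_heatmap(
    xk: float, yk: float, spec: TargetHeatmapSpec, h: int, w: int
) -> np.ndarray:
    """Normalised target splotch centred at pixel (xk, yk).

    Both kinds attain half their peak at axial distance sigma*sqrt(2 ln 2)
    from the centre; the exponential uses an L1 (diamond) profile with its
    decay constant chosen to match that radius.
    """
    if spec.kind == "none":
        raise ValueError("no target heatmap for kind='none'")
    if not (0 <= xk < w and 0 <= yk < h):
        raise ValueError(f"centre ({xk}, {yk}) outside {h}x{w} grid")
    xs = np.arange(w, dtype=float) - xk
    ys = np.arange(h, dtype=float) - yk
    dx, dy = np.meshgrid(xs, ys)
    if spec.kind == "gaussian":
        g = np.exp(-(dx**2 + dy**2) / (2.0 * spec.sigma**2))
    else:
        # half max at |d| = sigma*sqrt(2 ln 2) along either axis
        rate = math.log(2.0) / (spec.sigma * math.sqrt(2.0 * math.log(2.0)))
        g = np.exp(-rate * (np.abs(dx) + np.abs(dy)))
    return g / g.sum()


def js_divergence(p: np.ndarray, q: np.ndarray, atol: float = 1e-6) -> float:
    """Jensen-Shannon divergence (nats) of two normalised grids; symmetric,
    zero iff equal, bounded above by ln 2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for name, g in (("p", p), ("q", q)):
        if abs(g.sum() - 1.0) > atol or (g < 0).any():
            raise ValueError(f"grid {name} is not a normalised distribution")
    m = (p + q) / 2.0
    return float(_kl(p, m) / 2.0 + _kl(q, m) / 2.0)


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def total_loss(
    stage_coords: np.ndarray,
    truth: np.ndarray,
    stage2_probs: np.ndarray | None = None,
    targets: np.ndarray | None = None,
    spec: TargetHeatmapSpec = TargetHeatmapSpec(kind="none", sigma=1.0),
    lambda_js: float = 1.0,
    wing: WingParams = WingParams(),
    coord_scale: tuple[float, float] = (1.0, 1.0),
) -> float:
    """The single-image training objective.

    Mean over landmarks (and sum over stages) of Wing losses on the x and y
    coordinate residuals, plus ``lambda_js`` times the mean Jensen-Shannon
    divergence between stage-2 heatmaps and their targets when
    ``spec.kind != 'none'``.  ``stage_coords`` is (n_stages, K, 2) and
    ``truth`` is (K, 2), all in the DSNT normalised frame;  ``coord_scale``
    converts residuals into the metric the Wing parameters are expressed in
    (e.g. half the heatmap grid dimensions for a pixel metric).
    """
    stage_coords = np.asarray(stage_coords, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if stage_coords.ndim != 3 or stage_coords.shape[1:] != truth.shape:
        raise ValueError(
            f"shape mismatch: stage_coords {stage_coords.shape} vs truth {truth.shape}"
        )
    k = truth.shape[0]
    res = (stage_coords - truth[None]) * np.asarray(coord_scale)
    loss = float(wing_loss(res, wing).sum()) / k
    if spec.kind != "none":
        if stage2_probs is None or targets is None:
            raise ValueError("regularisation requested but stage-2 heatmaps/targets missing")
        if stage2_probs.shape != targets.shape:
            raise ValueError("stage-2 heatmap / target shape mismatch")
        js = [js_divergence(p, t) for p, t in zip(stage2_probs, targets)]
        loss += lambda_js * float(np.mean(js))
    return loss
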