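"""Training loop, augmentation, weighted-error metric and model selection.

The selection metric is the *weighted localisation error*: each landmark's
Euclidean error divided by the distance from that annotated landmark to its
nearest annotated neighbour on the same image, a dimensionless measure of
how far a prediction strays relative to the local landmark density.  Per
landmark the median over images is taken (error distributions are skewed),
and a candidate model is scored by the maximum of those medians; the best
candidate minimises that maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform, gaussian_filter

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .heatmaps import TargetHeatmapSpec, WingParams, pixel_to_normalized, target_heatmap
from .network import ModelConfig, SpineLandmarkNet, coords_to_input_pixels, normalize_intensity
from .schema import REGION_OF, LandmarkID, LandmarkSet, Region, VERTEBRAL_CENTERS


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule and augmentation ranges."""

    epochs: int = 120
    early_stop_patience: int = 20
    lr: float = 0.005
    lr_drop_epoch: int = 100
    lr_drop_to: float = 0.0005
    batch_size: int = 8
    seed: int = 0
    scale_range: tuple[float, float] = (0.8, 1.0)
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    blur_range: tuple[float, float] = (0.0, 0.1)
    wing: WingParams = WingParams()
    heatmap: TargetHeatmapSpec = TargetHeatmapSpec(kind="none", sigma=1.0)
    lambda_js: float = 1.0
    augment: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.early_stop_patience < self.epochs):
            raise ValueError("early_stop_patience must be in (0, epochs)")
        if self.scale_range[0] > self.scale_range[1] or self.scale_range[0] <= 0:
            raise ValueError(f"bad scale_range {self.scale_range}")
        if self.rotation_range[0] > self.rotation_range[1]:
            raise ValueError(f"bad rotation_range {self.rotation_range}")


# ---------------------------------------------------------------------------
# augmentation


def _affine_apply(xy: np.ndarray, scale: float, angle_deg: float, center: np.ndarray) -> np.ndarray:
    t = math.radians(angle_deg)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    return (xy - center) @ (scale * rot).T + center


def augment(
    image: np.ndarray,
    landmarks: LandmarkSet,
    rng: np.random.Generator,
    cfg: TrainConfig = TrainConfig(),
    max_redraws: int = 25,
) -> tuple[np.ndarray, LandmarkSet]:
    """Random similarity transform about the canvas centre plus Gaussian
    blur; the same transform is applied to pixels and landmark coordinates
    (blur leaves landmarks untouched).  Draws pushing any landmark outside
    the canvas are rejected and redrawn."""
    h, w = image.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    xy = landmarks.as_array()
    for _ in range(max_redraws):
        scale = rng.uniform(*cfg.scale_range)
        angle = rng.uniform(*cfg.rotation_range)
        strength = rng.uniform(*cfg.blur_range)
        new_xy = _affine_apply(xy, scale, angle, center)
        if (new_xy[:, 0].min() >= 0 and new_xy[:, 0].max() <= w - 1
                and new_xy[:, 1].min() >= 0 and new_xy[:, 1].max() <= h - 1):
            break
    else:  # fall back to the identity draw
        scale, angle, strength, new_xy = 1.0, 0.0, 0.0, xy

    if scale == 1.0 and angle == 0.0:
        out = image.copy()
    else:
        # ndimage maps output -> input; supply the inverse similarity in
        # (row, col) order
        t = math.radians(angle)
        rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        inv = rot.T / scale  # acts on (x, y)
        inv_rc = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
        center_rc = center[::-1]
        offset = center_rc - inv_rc @ center_rc
        out = affine_transform(image, inv_rc, offset=offset, order=1, mode="constant", cval=0.0)
    if strength > 0:
        out = gaussian_filter(out, sigma=10.0 * strength)
    return out, landmarks.with_points(new_xy)


# ---------------------------------------------------------------------------
# weighted localisation error


def nearest_neighbor_distances(truth_xy: np.ndarray) -> np.ndarray:
    """Per-landmark distance to the nearest *other* annotated landmark."""
    diff = truth_xy[:, None, :] - truth_xy[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, np.inf)
    mins = d.min(axis=1)
    if np.any(mins == 0):
        raise ValueError("duplicate annotated landmarks: weighted error undefined")
    return mins


def weighted_errors_from_arrays(pred_xy: np.ndarray, truth_xy: np.ndarray) -> np.ndarray:
    err = np.linalg.norm(pred_xy - truth_xy, axis=-1)
    return err / nearest_neighbor_distances(truth_xy)


def weighted_localisation_error(pred: LandmarkSet, truth: LandmarkSet) -> np.ndarray:
    """45 dimensionless errors (order follows the LandmarkID enumeration)."""
    return weighted_errors_from_arrays(pred.as_array(), truth.as_array())


# ---------------------------------------------------------------------------
# model selection


@dataclass(frozen=True)
class SelectionReport:
    """Per-candidate weighted-error summaries (medians per landmark, the
    max-median score, and the IQR of the score-setting landmark)."""

    per_landmark_medians: dict[str, np.ndarray]
    max_median: dict[str, float]
    argmax_landmark: dict[str, int]
    iqr_of_max_landmark: dict[str, float]
    winners: tuple[str, ...]

    def best(self) -> str:
        return self.winners[0]


def select_model(candidates: dict[str, np.ndarray], n_winners: int = 2) -> SelectionReport:
    """Score candidate runs by max-median weighted error.

    ``candidates`` maps a candidate name to an (images x landmarks) array of
    weighted localisation errors on the validation folds.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    medians, scores, argmaxes, iqrs = {}, {}, {}, {}
    for name, errs in candidates.items():
        errs = np.asarray(errs, dtype=float)
        if errs.ndim == 1:
            errs = errs[:, None]
        if errs.size == 0:
            raise ValueError(f"candidate {name!r} has no errors")
        med = np.median(errs, axis=0)
        j = int(np.argmax(med))
        medians[name] = med
        scores[name] = float(med[j])
        argmaxes[name] = j
        q75, q25 = np.percentile(errs[:, j], [75, 25])
        iqrs[name] = float(q75 - q25)
    order = sorted(scores, key=lambda k: scores[k])
    return SelectionReport(
        per_landmark_medians=medians,
        max_median=scores,
        argmax_landmark=argmaxes,
        iqr_of_max_landmark=iqrs,
        winners=tuple(order[:n_winners]),
    )


def derive_sigma_grid(mean_intervertebral_px: float) -> tuple[float, list[float]]:
    """Heatmap-width grid from the mean inter-vertebral distance: the base
    width confines a Gaussian splotch (six sigma) within that distance."""
    if not (mean_intervertebral_px > 0):
        raise ValueError("mean inter-vertebral distance must be positive")
    d_sigma = round(mean_intervertebral_px / 6.0, 1)
    return d_sigma, [d_sigma, d_sigma / 2.0, d_sigma / 4.0]


def candidate_grid(d_sigma: float) -> dict[str, TargetHeatmapSpec]:
    """The 7-candidate hyperparameter grid: {gaussian, exponential} x three
    widths, plus no regularisation."""
    out: dict[str, TargetHeatmapSpec] = {"none": TargetHeatmapSpec(kind="none", sigma=1.0)}
    for kind in ("gaussian", "exponential"):
        for s in (d_sigma, d_sigma / 2.0, d_sigma / 4.0):
            out[f"{kind}-{s:g}"] = TargetHeatmapSpec(kind=kind, sigma=s)
    return out


def kfold_split(
    labels: list[str], k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold assignment stratified by class label."""
    labels_arr = np.asarray(labels)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(labels_arr), dtype=int)
    for cls in np.unique(labels_arr):
        idx = np.flatnonzero(labels_arr == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % k
    return [
        (np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f)) for f in range(k)
    ]


# ---------------------------------------------------------------------------
# dataset plumbing and the loop


@dataclass
class TrainResult:
    metrics: pd.DataFrame
    best_val_xi: float
    best_epoch: int
    stopped_early: bool
    stage1_final_xi: float
    stage2_final_xi: float


_AREAS = {
    Region.CERVICAL: "cervical",
    Region.THORACIC: "thoracic",
    Region.LUMBAR: "lumbar",
    Region.FEMORAL: "femoral",
}
#: landmarks entering the learning-speed analysis: vertebral centres plus
#: the femoral heads
SD_LANDMARKS = tuple(VERTEBRAL_CENTERS) + (
    LandmarkID.FEMORAL_HEAD_LEFT_CENTER,
    LandmarkID.FEMORAL_HEAD_RIGHT_CENTER,
)


def _pixels(img) -> np.ndarray:
    """Accept raw arrays or RadiographImage objects in datasets."""
    return img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)


def prepare_sample(
    image: np.ndarray, lm: LandmarkSet, input_size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(network input, normalised truth coords) for one already-sized pair."""
    h, w = input_size
    if image.shape != (h, w):
        raise ValueError(f"sample shape {image.shape} != model input {input_size}")
    xy = lm.as_array()
    truth = np.stack(
        [pixel_to_normalized(xy[:, 0], w), pixel_to_normalized(xy[:, 1], h)], axis=1
    )
    return normalize_intensity(image), truth


def _batch_loss(
    model: SpineLandmarkNet,
    images: np.ndarray,
    truth: np.ndarray,
    cfg: TrainConfig,
) -> Tensor:
    hh, wh = model.cfg.heatmap_size
    scale = np.array([wh / 2.0, hh / 2.0])  # wing metric: heatmap pixels
    out = model.forward_tensor(Tensor(images[:, None]), training=True)
    k = model.cfg.n_landmarks
    b = images.shape[0]
    loss = None
    for coords in out["coords"]:
        res = (coords - Tensor(truth)) * Tensor(scale)
        term = ad.wing(res, cfg.wing.w, cfg.wing.epsilon).sum() * (1.0 / (k * b))
        loss = term if loss is None else loss + term
    if cfg.heatmap.kind != "none":
        targets = np.empty((b, k, hh, wh))
        for i in range(b):
            for j in range(k):
                xpx = np.clip((truth[i, j, 0] * wh + wh + 1) / 2 - 1, 0, wh - 1)
                ypx = np.clip((truth[i, j, 1] * hh + hh + 1) / 2 - 1, 0, hh - 1)
                targets[i, j] = target_heatmap(float(xpx), float(ypx), cfg.heatmap, hh, wh)
        loss = loss + ad.js_to_target(out["probs"][1], targets) * cfg.lambda_js
    return loss


def _validate(
    model: SpineLandmarkNet, samples: list[tuple[np.ndarray, LandmarkSet]], batch_size: int
) -> dict:
    """Weighted errors for both stages plus stage-1 heatmap SDs per area."""
    from .evaluation import heatmap_sd

    h, w = model.cfg.input_size
    errs = {1: [], 2: []}
    sd_area_acc: dict[str, list[float]] = {v: [] for v in _AREAS.values()}
    order = tuple(LandmarkID)
    sd_idx = [order.index(lm) for lm in SD_LANDMARKS]
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        batch = np.stack([normalize_intensity(_pixels(img)) for img, _ in chunk])
        out = model.forward(batch)
        for stage in (1, 2):
            coords = out.stage_coords(stage)
            for row, (_, lm) in zip(coords, chunk):
                pred_px = coords_to_input_pixels(row, (h, w))
                errs[stage].append(weighted_errors_from_arrays(pred_px, lm.as_array()))
        probs1 = np.stack([_softmax(v) for v in out.heatmaps[0].values])
        sds = np.array([heatmap_sd(p) for p in probs1]) * model.cfg.heatmap_downsample
        for lm_id, idx in zip(SD_LANDMARKS, sd_idx):
            sd_area_acc[_AREAS[REGION_OF[lm_id]]].append(sds[idx])
    return {
        "errors": {s: np.array(errs[s]) for s in (1, 2)},
        "area_sd": {a: float(np.mean(v)) for a, v in sd_area_acc.items()},
    }


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = np.exp(scores - scores.max())
    return z / z.sum()


def _xi(errors: np.ndarray) -> float:
    """Max over landmarks of the median over images."""
    return float(np.median(errors, axis=0).max())


def train(
    model: SpineLandmarkNet,
    dataset: list[tuple[np.ndarray, LandmarkSet]],
    cfg: TrainConfig,
    val_dataset: list[tuple[np.ndarray, LandmarkSet]] | None = None,
) -> TrainResult:
    """Adam-optimised training with early stopping on the validation
    max-median weighted error; the best-scoring weights are restored at the
    end.

    ``dataset`` / ``val_dataset`` hold ([0,1] image, LandmarkSet) pairs at
    the model's input size.  Returns per-epoch metrics including the
    stage-1 heatmap SDs per anatomic area (the learning-speed log).
    """
    if val_dataset is None:
        n_val = max(1, len(dataset) // 5)
        val_dataset, dataset = dataset[:n_val], dataset[n_val:]
    rng = np.random.default_rng(cfg.seed)
    params = model.params()
    opt = Adam(params, lr=cfg.lr)
    rows = []
    best = (math.inf, -1, None)  # (val_xi, epoch, weights)
    stopped_early = False
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = cfg.lr_drop_to if epoch >= cfg.lr_drop_epoch else cfg.lr
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            imgs, truths = [], []
            for i in idx:
                img, lm = _pixels(dataset[i][0]), dataset[i][1]
                if cfg.augment:
                    img, lm = augment(img, lm, rng, cfg)
                x, t = prepare_sample(img, lm, model.cfg.input_size)
                imgs.append(x)
                truths.append(t)
            loss = _batch_loss(model, np.stack(imgs), np.stack(truths), cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={opt.lr}): aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val = _validate(model, val_dataset, cfg.batch_size)
        xi1, xi2 = _xi(val["errors"][1]), _xi(val["errors"][2])
        rows.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / max(1, n_batches),
                "val_xi": xi2,
                "val_xi_stage1": xi1,
                **{f"sd_{a}": v for a, v in val["area_sd"].items()},
            }
        )
        if xi2 < best[0]:
            best = (xi2, epoch, [p.data.copy() for p in params])
        elif epoch - best[1] >= cfg.early_stop_patience:
            stopped_early = True
            break
    if best[2] is not None:
        for p, w in zip(params, best[2]):
            p.data = w
    final = _validate(model, val_dataset, cfg.batch_size)
    return TrainResult(
        metrics=pd.DataFrame(rows),
        best_val_xi=best[0],
        best_epoch=best[1],
        stopped_early=stopped_early,
        stage1_final_xi=_xi(final["errors"][1]),
        stage2_final_xi=_xi(final["errors"][2]),
    )
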