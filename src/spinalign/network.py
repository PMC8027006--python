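"""Two-stage coarse-to-fine landmark network.

A residual-block encoder with feature-pyramid fusion produces one heatmap
per landmark; a refinement sub-network over the concatenated stage-1
features and heatmap logits produces the second, finer set.  Each stage is
terminated by a DSNT layer, so the network regresses coordinates directly
while remaining fully convolutional up to the read-out.

The architecture is organised around a census of trainable residual blocks
(25 in the default configuration): a stem convolution, three encoder levels
at 1/4, 1/8 and 1/16 resolution, upsample-and-add fusion back to the
heatmap resolution, a stage-1 head, and a stage-2 refinement chain.  The
block census and parameter count are pure functions of the configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .heatmaps import HeatmapStack, make_coord_grids, normalized_to_pixel
from .schema import LandmarkSet, RadiographImage, preprocess

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture configuration.

    ``n_residual_blocks`` is the trainable residual-block census; it must be
    at least 9 + ``stage2_refinement_depth`` so every structural slot
    (3 fusion blocks, two heads, three encoder levels) gets a block.
    """

    input_size: tuple[int, int] = (864, 480)  # (H, W)
    n_landmarks: int = 45
    n_residual_blocks: int = 25
    base_channels: int = 32
    heatmap_downsample: int = 4
    stage2_refinement_depth: int = 4

    def __post_init__(self) -> None:
        h, w = self.input_size
        ds = self.heatmap_downsample
        if ds not in (4, 8):
            raise ConfigError(f"heatmap_downsample must be 4 or 8, got {ds}")
        if h % ds or w % ds:
            raise ConfigError(f"input dims {h}x{w} not divisible by heatmap_downsample {ds}")
        n_enc = self.n_residual_blocks - (3 + 1 + self.stage2_refinement_depth + 1)
        if n_enc < 3:
            raise ConfigError(
                f"n_residual_blocks={self.n_residual_blocks} too small for "
                f"stage2_refinement_depth={self.stage2_refinement_depth}"
            )

    @property
    def heatmap_size(self) -> tuple[int, int]:
        return (
            self.input_size[0] // self.heatmap_downsample,
            self.input_size[1] // self.heatmap_downsample,
        )

    def encoder_blocks(self) -> tuple[int, int, int]:
        """Distribution of encoder residual blocks over the three levels."""
        n_enc = self.n_residual_blocks - (3 + 1 + self.stage2_refinement_depth + 1)
        base, rem = divmod(n_enc, 3)
        return (base, base + (1 if rem == 2 else 0), base + (1 if rem >= 1 else 0))


@dataclass(frozen=True)
class StageOutputs:
    """Heatmaps and DSNT coordinates for both stages of one forward pass."""

    heatmaps: tuple[HeatmapStack, HeatmapStack]  # per-stage, first image only
    coords: np.ndarray  # (n_stages=2, B, K, 2) normalised coordinates

    def stage_coords(self, stage: int) -> np.ndarray:
        return self.coords[stage - 1]


# ---------------------------------------------------------------------------
# layers


class _Conv:
    def __init__(self, rng, cin, cout, k, stride=1, bias=True):
        fan_in = cin * k * k
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride, self.pad = stride, k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class _BN:
    def __init__(self, c):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var, training
        )

    def params(self):
        return [self.gamma, self.beta]


class _ResBlock:
    """Two 3x3 convolutions with a skip connection; a 1x1 convolution is
    added on the skip path when the input and output shapes differ."""

    def __init__(self, rng, cin, cout, stride=1):
        self.conv1 = _Conv(rng, cin, cout, 3, stride=stride, bias=False)
        self.bn1 = _BN(cout)
        self.conv2 = _Conv(rng, cout, cout, 3, bias=False)
        self.bn2 = _BN(cout)
        self.proj = None
        self.proj_bn = None
        if stride != 1 or cin != cout:
            self.proj = _Conv(rng, cin, cout, 1, stride=stride, bias=False)
            self.proj_bn = _BN(cout)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        out = self.bn1(self.conv1(x), training).relu()
        out = self.bn2(self.conv2(out), training)
        skip = x if self.proj is None else self.proj_bn(self.proj(x), training)
        return (out + skip).relu()

    def params(self):
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            out += self.proj.params() + self.proj_bn.params()
        return out


# ---------------------------------------------------------------------------
# the model


class SpineLandmarkNet:
    """Two-stage heatmap network with DSNT read-out."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = cfg.base_channels
        k = cfg.n_landmarks
        n1, n2, n3 = cfg.encoder_blocks()
        self._blocks: list[_ResBlock] = []

        def res(cin, cout, stride=1):
            blk = _ResBlock(rng, cin, cout, stride)
            self._blocks.append(blk)
            return blk

        self.stem = _Conv(rng, 1, c, 3, stride=2, bias=False)
        self.stem_bn = _BN(c)
        self.enc1 = [res(c, c, 2)] + [res(c, c) for _ in range(n1 - 1)]  # /4
        self.enc2 = [res(c, 2 * c, 2)] + [res(2 * c, 2 * c) for _ in range(n2 - 1)]  # /8
        self.enc3 = [res(2 * c, 4 * c, 2)] + [res(4 * c, 4 * c) for _ in range(n3 - 1)]  # /16
        self.lat3 = _Conv(rng, 4 * c, c, 1)
        self.lat2 = _Conv(rng, 2 * c, c, 1)
        self.lat1 = _Conv(rng, c, c, 1)
        # three fusion blocks; their placement depends on the heatmap scale
        self.fuse_a = res(c, c)
        self.fuse_b = res(c, c)
        self.fuse_c = res(c, c)
        self.head1_block = res(c, c)
        self.head1_out = _Conv(rng, c, k, 1)
        # normalise the concatenated entry: stage-1 logit magnitudes grow as
        # that head sharpens and would otherwise saturate the refinement path
        self.stage2_in = _Conv(rng, c + k, c, 1, bias=False)
        self.stage2_bn = _BN(c)
        self.refine = [res(c, c) for _ in range(cfg.stage2_refinement_depth)]
        self.head2_block = res(c, c)
        self.head2_out = _Conv(rng, c, k, 1)
        hh, wh = cfg.heatmap_size
        self._xgrid, self._ygrid = make_coord_grids(hh, wh)

    # -- plumbing -----------------------------------------------------------

    def residual_block_count(self) -> int:
        return len(self._blocks)

    def params(self) -> list[Tensor]:
        out = self.stem.params() + self.stem_bn.params()
        for blk in self._blocks:
            out += blk.params()
        for conv in (self.lat3, self.lat2, self.lat1, self.head1_out, self.stage2_in, self.head2_out):
            out += conv.params()
        out += self.stage2_bn.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    # -- forward ------------------------------------------------------------

    def forward_tensor(self, x: Tensor, training: bool = False) -> dict:
        """Full two-stage forward pass on a (B, 1, H, W) batch."""
        cfg = self.cfg
        h = self.stem_bn(self.stem(x), training).relu()
        f1 = h
        for blk in self.enc1:
            f1 = blk(f1, training)  # /4
        f2 = f1
        for blk in self.enc2:
            f2 = blk(f2, training)  # /8
        f3 = f2
        for blk in self.enc3:
            f3 = blk(f3, training)  # /16

        p3 = self.lat3(f3)
        p2 = self.lat2(f2) + ad.crop2d(ad.upsample2x(p3), f2.shape[2], f2.shape[3])
        p2 = self.fuse_a(p2, training)
        if cfg.heatmap_downsample == 4:
            fused = self.lat1(f1) + ad.crop2d(ad.upsample2x(p2), f1.shape[2], f1.shape[3])
            fused = self.fuse_b(fused, training)
        else:  # fuse at /8
            fused = self.fuse_b(p2, training)
        fused = self.fuse_c(fused, training)

        logits1 = self.head1_out(self.head1_block(fused, training))
        s2 = self.stage2_bn(self.stage2_in(ad.concat([fused, logits1], axis=1)), training).relu()
        for blk in self.refine:
            s2 = blk(s2, training)
        logits2 = self.head2_out(self.head2_block(s2, training))

        probs1 = ad.softmax_hw(logits1)
        probs2 = ad.softmax_hw(logits2)
        coords1 = ad.dsnt_coords(probs1, self._xgrid, self._ygrid)
        coords2 = ad.dsnt_coords(probs2, self._xgrid, self._ygrid)
        return {
            "logits": (logits1, logits2),
            "probs": (probs1, probs2),
            "coords": (coords1, coords2),
        }

    def forward(self, batch: np.ndarray) -> StageOutputs:
        """Inference-mode forward; returns numpy stage outputs."""
        batch = np.asarray(batch, dtype=float)
        if batch.ndim == 2:
            batch = batch[None]
        if batch.ndim == 3:
            batch = batch[:, None]
        if batch.shape[2:] != tuple(self.cfg.input_size):
            raise ValueError(
                f"batch spatial shape {batch.shape[2:]} != input_size {self.cfg.input_size}"
            )
        out = self.forward_tensor(Tensor(batch), training=False)
        coords = np.stack([out["coords"][0].data, out["coords"][1].data])
        stacks = (
            HeatmapStack(out["logits"][0].data[0], stage=1),
            HeatmapStack(out["logits"][1].data[0], stage=2),
        )
        return StageOutputs(heatmaps=stacks, coords=coords)

    def predict_coords(self, batch: np.ndarray) -> np.ndarray:
        """Stage-2 normalised coordinates only (the inference path)."""
        return self.forward(batch).stage_coords(2)

    # -- checkpoints --------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params())}
        stats = {}
        for j, bn in enumerate(self._bn_layers()):
            stats[f"bn_{j}_mean"] = bn.running_mean
            stats[f"bn_{j}_var"] = bn.running_var
        return {**arrays, **stats}

    def _bn_layers(self) -> list[_BN]:
        bns = [self.stem_bn, self.stage2_bn]
        for blk in self._blocks:
            bns += [blk.bn1, blk.bn2] + ([blk.proj_bn] if blk.proj_bn is not None else [])
        return bns

    def save(self, path: str | Path) -> None:
        meta = {"schema_version": SCHEMA_VERSION, "seed": self.seed, "config": asdict(self.cfg)}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "SpineLandmarkNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["schema_version"] != SCHEMA_VERSION:
                raise ValueError(f"checkpoint schema {meta['schema_version']} unsupported")
            cfg_d = meta["config"]
            cfg_d["input_size"] = tuple(cfg_d["input_size"])
            model = cls(ModelConfig(**cfg_d), seed=meta["seed"])
            for i, p in enumerate(model.params()):
                p.data = data[f"param_{i}"].copy()
            for j, bn in enumerate(model._bn_layers()):
                bn.running_mean[...] = data[f"bn_{j}_mean"]
                bn.running_var[...] = data[f"bn_{j}_var"]
        return model


def build_model(cfg: ModelConfig, seed: int = 0) -> SpineLandmarkNet:
    """Deterministically initialised two-stage landmark network."""
    return SpineLandmarkNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# prediction on radiographs


def coords_to_input_pixels(coords: np.ndarray, input_size: tuple[int, int]) -> np.ndarray:
    """Map normalised (K, 2) coordinates to 0-based model-grid pixels."""
    h, w = input_size
    out = np.empty_like(coords)
    out[..., 0] = normalized_to_pixel(coords[..., 0], w)
    out[..., 1] = normalized_to_pixel(coords[..., 1], h)
    return out


def predict_landmarks(
    models: SpineLandmarkNet | list[SpineLandmarkNet],
    image: RadiographImage,
    anterior_direction: int = +1,
) -> LandmarkSet:
    """Run one or more trained models on a radiograph and return the
    (unweighted ensemble-averaged) landmark set in original pixels."""
    if isinstance(models, SpineLandmarkNet):
        models = [models]
    cfgs = {(m.cfg.input_size, m.cfg.n_landmarks) for m in models}
    if len(cfgs) != 1:
        raise ValueError("ensemble members disagree on landmark schema/input size")
    cfg = models[0].cfg
    grid, tf = preprocess(image, target_size=cfg.input_size)
    batch = normalize_intensity(grid)[None]
    per_model = []
    for m in models:
        coords = m.predict_coords(batch)[0]  # (K, 2) normalised
        per_model.append(coords_to_input_pixels(coords, cfg.input_size))
    mean_px = np.mean(per_model, axis=0)
    orig = tf.inverse(mean_px)
    h0, w0 = image.shape
    orig[:, 0] = np.clip(orig[:, 0], 0, w0 - 1)
    orig[:, 1] = np.clip(orig[:, 1], 0, h0 - 1)
    return LandmarkSet.from_array(
        orig, image.pixel_spacing, (h0, w0), anterior_direction
    )


def normalize_intensity(grid: np.ndarray) -> np.ndarray:
    """Map a [0, 1] image to the zero-centred range the network expects."""
    return (np.asarray(grid, dtype=float) - 0.5) * 2.0
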