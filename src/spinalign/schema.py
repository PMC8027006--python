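"""Landmark vocabulary, coordinate conventions and annotation / image I/O.

The annotation unit is a :class:`LandmarkSet`: 45 named points on a
whole-spine lateral radiograph, expressed as 0-based pixel coordinates
(``x`` = column, ``y`` = row, y increasing downward, cranial = -y) plus an
isotropic physical pixel spacing in mm.  22 of the points are *specific*
anatomic landmarks (endplate corners, sacral endplate edges, the C2 dens and
the two femoral-head centres); the remaining 23 are the vertebral-body
centres from C2 to L5, used to trace the spinal curve.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np


class Region(str, enum.Enum):
    CERVICAL = "cervical"
    THORACIC = "thoracic"
    LUMBAR = "lumbar"
    SACRAL = "sacral"
    FEMORAL = "femoral"


def _vertebral_levels() -> list[str]:
    return (
        [f"C{i}" for i in range(2, 8)]
        + [f"T{i}" for i in range(1, 13)]
        + [f"L{i}" for i in range(1, 6)]
    )


_SPECIFIC = [
    "C2_DENS_CENTER",
    "C2_ANTEROINFERIOR",
    "C2_POSTEROINFERIOR",
    "C7_ANTEROINFERIOR",
    "C7_POSTEROSUPERIOR",
    "C7_POSTEROINFERIOR",
    "T1_ANTEROSUPERIOR",
    "T1_POSTEROSUPERIOR",
    "T5_ANTEROSUPERIOR",
    "T5_POSTEROSUPERIOR",
    "T5_ANTEROINFERIOR",
    "T5_POSTEROINFERIOR",
    "T12_ANTEROINFERIOR",
    "T12_POSTEROINFERIOR",
    "L1_ANTEROSUPERIOR",
    "L1_POSTEROSUPERIOR",
    "L4_ANTEROSUPERIOR",
    "L4_POSTEROSUPERIOR",
    "S1_ANTERIOR_EDGE",
    "S1_POSTERIOR_EDGE",
    "FEMORAL_HEAD_LEFT_CENTER",
    "FEMORAL_HEAD_RIGHT_CENTER",
]

LandmarkID = enum.Enum(  # type: ignore[misc]
    "LandmarkID", _SPECIFIC + [f"CENTER_{lvl}" for lvl in _vertebral_levels()]
)


def _region_of(name: str) -> Region:
    if name.startswith("FEMORAL"):
        return Region.FEMORAL
    if name.startswith("S1"):
        return Region.SACRAL
    level = name.split("_")[0] if not name.startswith("CENTER") else name.split("_")[1]
    return {"C": Region.CERVICAL, "T": Region.THORACIC, "L": Region.LUMBAR}[level[0]]


REGION_OF: dict[LandmarkID, Region] = {lm: _region_of(lm.name) for lm in LandmarkID}

#: the subset of IDs wired into the 18 spinopelvic parameters (the remaining
#: vertebral centres only trace the curve).
USED_FOR_PARAMETERS: frozenset[LandmarkID] = frozenset(
    [LandmarkID[n] for n in _SPECIFIC]
    + [LandmarkID[n] for n in ("CENTER_C7", "CENTER_T1", "CENTER_L1")]
)

VERTEBRAL_CENTERS: tuple[LandmarkID, ...] = tuple(
    LandmarkID[f"CENTER_{lvl}"] for lvl in _vertebral_levels()
)

assert len(LandmarkID) == 45


class SchemaError(ValueError):
    """Annotation file violates the 45-landmark schema."""


@dataclass(frozen=True)
class LandmarkSet:
    """45 named points in 0-based pixel coordinates plus physical scale.

    Parameters
    ----------
    points
        Mapping from every :class:`LandmarkID` to ``(x, y)`` pixel
        coordinates (x = column, y = row).
    pixel_spacing
        Isotropic physical pixel size in mm/px; must be positive.
    image_size
        ``(height, width)`` of the image the coordinates live in.
    anterior_direction
        ``+1`` if +x points toward the patient's front, ``-1`` otherwise.
    """

    points: Mapping[LandmarkID, tuple[float, float]]
    pixel_spacing: float
    image_size: tuple[int, int]
    anterior_direction: int = +1

    def __post_init__(self) -> None:
        missing = [lm.name for lm in LandmarkID if lm not in self.points]
        if missing:
            raise SchemaError(f"{missing[0]} absent")
        if len(self.points) != 45:
            extra = [k for k in self.points if k not in LandmarkID]
            raise SchemaError(f"unexpected landmark keys: {extra}")
        if not (self.pixel_spacing > 0):
            raise SchemaError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if self.anterior_direction not in (+1, -1):
            raise SchemaError("anterior_direction must be +1 or -1")
        h, w = self.image_size
        for lm, (x, y) in self.points.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise SchemaError(f"{lm.name}: non-finite coordinate ({x}, {y})")
            if not (0 <= x < w and 0 <= y < h):
                raise SchemaError(
                    f"{lm.name}: ({x}, {y}) outside image of size {h}x{w}"
                )

    def __getitem__(self, lm: LandmarkID) -> tuple[float, float]:
        return self.points[lm]

    def as_array(self, order: tuple[LandmarkID, ...] | None = None) -> np.ndarray:
        """(45, 2) array of (x, y) rows in ``order`` (default: enum order)."""
        order = order or tuple(LandmarkID)
        return np.array([self.points[lm] for lm in order], dtype=float)

    @classmethod
    def from_array(
        cls,
        xy: np.ndarray,
        pixel_spacing: float,
        image_size: tuple[int, int],
        anterior_direction: int = +1,
        order: tuple[LandmarkID, ...] | None = None,
    ) -> "LandmarkSet":
        order = order or tuple(LandmarkID)
        pts = {lm: (float(x), float(y)) for lm, (x, y) in zip(order, xy)}
        return cls(pts, pixel_spacing, image_size, anterior_direction)

    def with_points(self, xy: np.ndarray) -> "LandmarkSet":
        return LandmarkSet.from_array(
            xy, self.pixel_spacing, self.image_size, self.anterior_direction
        )

    def translate(self, dx: float, dy: float) -> "LandmarkSet":
        return self.with_points(self.as_array() + np.array([dx, dy]))


@dataclass(frozen=True)
class RadiographImage:
    """A grayscale radiograph with physical pixel spacing attached."""

    pixels: np.ndarray  # 2-D float array, intensities in [0, 1]
    pixel_spacing: float
    source: str = "<memory>"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or 0 in self.pixels.shape:
            raise ValueError(f"expected a non-empty 2-D image, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if not (self.pixel_spacing > 0):
            raise ValueError("pixel_spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# annotation I/O


def save_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    """Write the JSON landmark dialect (coordinates preserved bit-exactly)."""
    payload = {
        "pixel_spacing_mm": lm.pixel_spacing,
        "image_size": list(lm.image_size),
        "anterior_direction": "+x" if lm.anterior_direction > 0 else "-x",
        "points": {k.name: [x, y] for k, (x, y) in lm.points.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_landmarks(
    path: str | Path,
    pixel_spacing: float | None = None,
    image_size: tuple[int, int] | None = None,
) -> LandmarkSet:
    """Read a landmark file in the package's JSON or CSV dialect.

    The CSV dialect (columns ``landmark,x,y``) carries no metadata, so
    ``pixel_spacing`` and ``image_size`` must then be supplied.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pts = _read_csv_points(path)
        if pixel_spacing is None or image_size is None:
            raise SchemaError(
                "CSV landmark files carry no pixel_spacing/image_size; pass them explicitly"
            )
        anterior = +1
    else:
        data = json.loads(path.read_text())
        pts = {}
        for name, xy in data["points"].items():
            if name not in LandmarkID.__members__:
                raise SchemaError(f"unknown landmark ID {name!r}")
            key = LandmarkID[name]
            if key in pts:
                raise SchemaError(f"duplicate landmark ID {name}")
            pts[key] = _coerce_xy(name, xy)
        pixel_spacing = float(data["pixel_spacing_mm"])
        image_size = tuple(data["image_size"])  # type: ignore[assignment]
        anterior = -1 if data.get("anterior_direction", "+x") == "-x" else +1
    return LandmarkSet(pts, pixel_spacing, image_size, anterior)  # type: ignore[arg-type]


def _coerce_xy(name: str, xy) -> tuple[float, float]:
    try:
        x, y = float(xy[0]), float(xy[1])
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{name}: non-numeric coordinate {xy!r}") from exc
    return x, y


def _read_csv_points(path: Path) -> dict[LandmarkID, tuple[float, float]]:
    pts: dict[LandmarkID, tuple[float, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            name = row["landmark"].strip()
            if name not in LandmarkID.__members__:
                raise SchemaError(f"unknown landmark ID {name!r}")
            key = LandmarkID[name]
            if key in pts:
                raise SchemaError(f"duplicate landmark ID {name}")
            pts[key] = _coerce_xy(name, (row["x"], row["y"]))
    return pts


def save_landmarks_csv(lm: LandmarkSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["landmark", "x", "y"])
        for k, (x, y) in lm.points.items():
            writer.writerow([k.name, repr(x), repr(y)])


# ---------------------------------------------------------------------------
# image I/O


class MissingSpacingError(ValueError):
    """The image has no physical scale and none was supplied."""


def load_radiograph(path: str | Path, pixel_spacing: float | None = None) -> RadiographImage:
    """Load a DICOM or PNG radiograph as a [0, 1] grayscale image.

    DICOM spacing is taken from PixelSpacing / ImagerPixelSpacing; PNG files
    carry none, so ``pixel_spacing`` must be supplied.  16-bit inputs are
    rescaled by their dtype range.
    """
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"} or _looks_like_dicom(path):
        return _load_dicom(path, pixel_spacing)
    import imageio.v3 as iio

    raw = iio.imread(path)
    dtype = raw.dtype
    if raw.ndim == 3:  # collapse any colour channels
        raw = raw[..., :3].mean(axis=-1)
    arr = raw.astype(float)
    if np.issubdtype(dtype, np.integer):
        arr = arr / np.iinfo(dtype).max
    if pixel_spacing is None:
        raise MissingSpacingError(
            f"{path.name}: no physical scale; mm-valued parameters need a pixel spacing"
        )
    return RadiographImage(arr, float(pixel_spacing), source=str(path))


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _load_dicom(path: Path, pixel_spacing: float | None) -> RadiographImage:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-frame grayscale DICOM")
    lo, hi = float(arr.min()), float(arr.max())
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    spacing = pixel_spacing
    if spacing is None:
        tag = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
        if tag is None:
            raise MissingSpacingError(
                f"{path.name}: DICOM has no PixelSpacing/ImagerPixelSpacing and no override given"
            )
        spacing = float(tag[0])
    return RadiographImage(arr, float(spacing), source=str(path))


# ---------------------------------------------------------------------------
# preprocessing to the model grid


@dataclass(frozen=True)
class PreprocessTransform:
    """Affine record mapping original pixels to model-grid pixels.

    forward: p_model = p_orig * scale + (scale - 1) / 2 + offset
    (the middle term maps pixel centres under uniform resampling).
    """

    scale: float
    offset_x: float
    offset_y: float
    original_size: tuple[int, int]
    target_size: tuple[int, int]

    def forward(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        shift = (self.scale - 1.0) / 2.0
        return xy * self.scale + shift + np.array([self.offset_x, self.offset_y])

    def inverse(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        shift = (self.scale - 1.0) / 2.0
        return (xy - np.array([self.offset_x, self.offset_y]) - shift) / self.scale


def preprocess(
    image: RadiographImage, target_size: tuple[int, int] = (864, 480)
) -> tuple[np.ndarray, PreprocessTransform]:
    """Resize (aspect-preserving) and pad an image to the model grid.

    Returns the ``target_size`` float array and the invertible transform
    record.  Padding is split equally left/right; any vertical remainder is
    padded at the bottom.
    """
    from skimage.transform import resize

    h0, w0 = image.shape
    ht, wt = target_size
    scale = min(ht / h0, wt / w0)
    hn, wn = max(1, round(h0 * scale)), max(1, round(w0 * scale))
    resized = resize(image.pixels, (hn, wn), order=1, anti_aliasing=scale < 1.0)
    pad_x = (wt - wn) // 2
    out = np.zeros((ht, wt), dtype=float)
    out[:hn, pad_x : pad_x + wn] = resized
    return out, PreprocessTransform(
        scale=scale,
        offset_x=float(pad_x),
        offset_y=0.0,
        original_size=(h0, w0),
        target_size=target_size,
    )
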