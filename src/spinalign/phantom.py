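"""Parametric sagittal spine phantoms.

Generates deterministic (image, ground-truth landmark) pairs that emulate a
whole-spine lateral radiograph: 23 vertebral bodies (C2..L5) stacked along a
curve whose regional endplate tilts realise requested cervical lordosis,
thoracic kyphosis, lumbar lordosis and pelvic incidence; a sacrum with an
explicit superior endplate; and two offset femoral-head circles whose
midpoint is the hip axis.  Landmarks are exact by construction, so the
geometry engine recovers the requested curvatures up to floating-point
error - this closes the generator/measurement loop and makes every other
module testable without clinical data.

Pathology classes mimic the composition of a clinical dataset: ``scoliosis``
(mid-thoracic vertebral overlap and contrast loss, as a lateral film shows
scoliosis), ``kyphosis`` (drawn with larger thoracic kyphosis by the spec
sampler) and ``implant`` (bright posterior rods).  The intensity model
(flat fills, additive Gaussian plus mild speckle noise, simple occluders)
is deliberately non-physical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk, polygon

from .schema import LandmarkID as L
from .schema import LandmarkSet, RadiographImage, VERTEBRAL_CENTERS

PATHOLOGIES = ("none", "scoliosis", "kyphosis", "implant")

#: class mix of the emulated dataset (scoliosis/kyphosis/implant shares)
CLASS_WEIGHTS = {"scoliosis": 1041 / 2210, "kyphosis": 466 / 2210, "implant": 703 / 2210}

_BONE = 0.55  # polygon fill intensity
_ROD = 0.95  # implant rod intensity


class PhantomError(RuntimeError):
    """Requested curvatures cannot be realised without self-intersection."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic radiograph.

    Curvatures are in degrees and follow the measurement conventions of the
    geometry engine (lordosis/kyphosis positive).  ``seed`` fully
    determines the output.
    """

    seed: int = 0
    canvas: tuple[int, int] = (864, 480)  # (H, W) px
    pixel_spacing: float = 0.8  # mm/px
    cervical_lordosis: float = 9.4
    thoracic_kyphosis: float = 37.7
    lumbar_lordosis: float = 47.0
    pelvic_incidence: float = 51.6
    vertebra_height: float = 0.62  # C2 body height, abstract units
    caudal_growth: float = 0.03  # per-level size growth toward L5
    pathology: str = "none"
    noise: float = 0.05
    rib_occluders: bool = True
    shoulder_occluder: bool = True

    def __post_init__(self) -> None:
        if self.pathology not in PATHOLOGIES:
            raise ValueError(f"unknown pathology {self.pathology!r}")
        bounds = {
            "cervical_lordosis": (-25, 40),
            "thoracic_kyphosis": (5, 80),
            "lumbar_lordosis": (10, 80),
            "pelvic_incidence": (25, 90),
        }
        for name, (lo, hi) in bounds.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside plausible range [{lo}, {hi}]")
        if self.vertebra_height <= 0 or self.noise < 0:
            raise ValueError("vertebra_height must be > 0 and noise >= 0")


# caudal -> cranial body order
_BODIES = [f"L{i}" for i in range(5, 0, -1)] + [f"T{i}" for i in range(12, 0, -1)] + [
    f"C{i}" for i in range(7, 1, -1)
]


def _e(theta_deg: float) -> np.ndarray:
    """Anterior unit vector of an endplate with tilt ``theta`` (anterior-up
    positive) in image coordinates (x anterior, y down)."""
    t = math.radians(theta_deg)
    return np.array([math.cos(t), -math.sin(t)])


def _n(theta_deg: float) -> np.ndarray:
    """Cranial unit normal of the same endplate."""
    t = math.radians(theta_deg)
    return np.array([-math.sin(t), -math.cos(t)])


def _region_profiles(spec: PhantomSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Endplate tilt sequences per region (caudal->cranial), with the
    closure-constrained endplates exact and the rest jittered."""
    ss = 0.696 * spec.pelvic_incidence  # sacral slope share of PI
    th_s1 = -ss
    delta = 2.0  # junctional disc offset, deg

    lum = np.linspace(th_s1 + delta, th_s1 + spec.lumbar_lordosis, 6)
    th_t12i = lum[-1] + delta
    tho = np.linspace(th_t12i, th_t12i - spec.thoracic_kyphosis, 13)
    th_c7i = tho[-1] + delta
    # the cervical constraint lives on the C2 *inferior* endplate (index 5
    # of 6), so the linear profile extends 6/5 of the lordosis to its top
    cer = np.linspace(th_c7i, th_c7i + spec.cervical_lordosis * 6.0 / 5.0, 7)

    constrained = {("lumbar", 5), ("thoracic", 0), ("thoracic", 12), ("cervical", 0), ("cervical", 5)}
    profiles = {"lumbar": lum, "thoracic": tho, "cervical": cer}
    for region, arr in profiles.items():
        jitter = rng.uniform(-1.0, 1.0, size=arr.size)
        for i in range(arr.size):
            if (region, i) not in constrained:
                arr[i] += jitter[i]
    if np.any(np.abs(np.concatenate(list(profiles.values()))) > 85):
        raise PhantomError("endplate tilts beyond +/-85 deg: cannot stack bodies")
    profiles["theta_s1"] = np.array([th_s1])
    profiles["ss"] = np.array([ss])
    return profiles


@dataclass
class _Geometry:
    """Phantom geometry in pixel coordinates (internal)."""

    landmarks: dict
    corners: dict  # body level -> (inf_ant, inf_post, sup_ant, sup_post)
    centers: dict
    sacrum_poly: np.ndarray
    hip: np.ndarray
    fem_left: np.ndarray
    fem_right: np.ndarray
    fem_radius: float
    rod_path: np.ndarray | None
    units_per_px: float


def _build_geometry(spec: PhantomSpec, rng: np.random.Generator) -> _Geometry:
    prof = _region_profiles(spec, rng)
    th_s1 = float(prof["theta_s1"][0])
    ss = float(prof["ss"][0])
    pt = spec.pelvic_incidence - ss

    heights = {}
    for idx, body in enumerate(_BODIES):  # idx 0 = L5 (largest)
        level_from_top = len(_BODIES) - 1 - idx
        heights[body] = spec.vertebra_height * (1 + spec.caudal_growth) ** level_from_top

    # sacral endplate at the origin
    m = np.zeros(2)
    ws = 0.62 * heights["L5"] * 1.6
    s1a, s1p = m + ws * _e(th_s1), m - ws * _e(th_s1)

    # hip axis placed to realise PI = PT + SS exactly
    tpt = math.radians(pt)
    hip = m + 2.2 * np.array([math.sin(tpt), math.cos(tpt)])
    fem_offset = np.array([0.45, 0.22])
    fem_l, fem_r = hip + fem_offset, hip - fem_offset
    fem_radius = 0.52

    # stack bodies caudal -> cranial
    tilts: list[tuple[float, float]] = []
    for region, n_b in (("lumbar", 5), ("thoracic", 12), ("cervical", 6)):
        arr = prof[region]
        tilts += [(float(arr[i]), float(arr[i + 1])) for i in range(n_b)]

    corners, centers = {}, {}
    p_inf = m + 0.30 * heights["L5"] * _n(th_s1)
    prev_y = math.inf
    for body, (t_inf, t_sup) in zip(_BODIES, tilts):
        h, w = heights[body], 1.6 * heights[body]
        p_sup = p_inf + h * _n((t_inf + t_sup) / 2)
        c_ia, c_ip = p_inf + (w / 2) * _e(t_inf), p_inf - (w / 2) * _e(t_inf)
        c_sa, c_sp = p_sup + (w / 2) * _e(t_sup), p_sup - (w / 2) * _e(t_sup)
        center = (p_inf + p_sup) / 2
        if center[1] >= prev_y:
            raise PhantomError(f"spinal curve folds at {body}")
        prev_y = center[1]
        corners[body] = (c_ia, c_ip, c_sa, c_sp)
        centers[body] = center
        p_inf = p_sup + 0.28 * h * _n(t_sup)

    c2_sup_mid = (corners["C2"][2] + corners["C2"][3]) / 2
    t_c2_sup = tilts[-1][1]
    dens = c2_sup_mid + 0.45 * heights["C2"] * _n(t_c2_sup)

    sacrum_poly = np.array(
        [s1a, s1p, s1p + np.array([-0.9, 1.6]), s1a + np.array([-0.2, 1.9])]
    )

    lms = {
        L.C2_DENS_CENTER: dens,
        L.C2_ANTEROINFERIOR: corners["C2"][0],
        L.C2_POSTEROINFERIOR: corners["C2"][1],
        L.C7_ANTEROINFERIOR: corners["C7"][0],
        L.C7_POSTEROSUPERIOR: corners["C7"][3],
        L.C7_POSTEROINFERIOR: corners["C7"][1],
        L.T1_ANTEROSUPERIOR: corners["T1"][2],
        L.T1_POSTEROSUPERIOR: corners["T1"][3],
        L.T5_ANTEROSUPERIOR: corners["T5"][2],
        L.T5_POSTEROSUPERIOR: corners["T5"][3],
        L.T5_ANTEROINFERIOR: corners["T5"][0],
        L.T5_POSTEROINFERIOR: corners["T5"][1],
        L.T12_ANTEROINFERIOR: corners["T12"][0],
        L.T12_POSTEROINFERIOR: corners["T12"][1],
        L.L1_ANTEROSUPERIOR: corners["L1"][2],
        L.L1_POSTEROSUPERIOR: corners["L1"][3],
        L.L4_ANTEROSUPERIOR: corners["L4"][2],
        L.L4_POSTEROSUPERIOR: corners["L4"][3],
        L.S1_ANTERIOR_EDGE: s1a,
        L.S1_POSTERIOR_EDGE: s1p,
        L.FEMORAL_HEAD_LEFT_CENTER: fem_l,
        L.FEMORAL_HEAD_RIGHT_CENTER: fem_r,
    }
    for body in _BODIES:
        lms[L[f"CENTER_{body}"]] = centers[body]

    rod_path = None
    if spec.pathology == "implant":
        # posterior rod spanning nine instrumented levels
        span = ["T9", "T10", "T11", "T12", "L1", "L2", "L3", "L4", "L5"]
        rod_path = np.array([corners[b][1] + np.array([-0.30, 0.0]) for b in span])

    # fit everything into the canvas with a margin (uniform scale + shift,
    # angle-preserving)
    pts = np.vstack(
        [np.array(list(lms.values())), sacrum_poly,
         fem_l + fem_radius, fem_l - fem_radius, fem_r + fem_radius, fem_r - fem_radius]
    )
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    hc, wc = spec.canvas
    margin = 0.06
    scale = min(wc * (1 - 2 * margin) / (hi[0] - lo[0]), hc * (1 - 2 * margin) / (hi[1] - lo[1]))
    shift = np.array([wc, hc]) / 2 - scale * (lo + hi) / 2

    def to_px(p: np.ndarray) -> np.ndarray:
        return p * scale + shift

    return _Geometry(
        landmarks={k: to_px(v) for k, v in lms.items()},
        corners={b: tuple(to_px(c) for c in cs) for b, cs in corners.items()},
        centers={b: to_px(c) for b, c in centers.items()},
        sacrum_poly=to_px(sacrum_poly),
        hip=to_px(hip),
        fem_left=to_px(fem_l),
        fem_right=to_px(fem_r),
        fem_radius=fem_radius * scale,
        rod_path=to_px(rod_path) if rod_path is not None else None,
        units_per_px=1.0 / scale,
    )


def _fill_poly(img: np.ndarray, pts: np.ndarray, value: float, additive: bool = False) -> None:
    rr, cc = polygon(pts[:, 1], pts[:, 0], shape=img.shape)
    if additive:
        img[rr, cc] += value
    else:
        img[rr, cc] = np.maximum(img[rr, cc], value)


def _thick_line(img: np.ndarray, path: np.ndarray, half_width: float, value: float) -> None:
    for p, q in zip(path[:-1], path[1:]):
        d = q - p
        norm = math.hypot(*d)
        if norm == 0:
            continue
        t = np.array([-d[1], d[0]]) / norm * half_width
        _fill_poly(img, np.array([p + t, q + t, q - t, p - t]), value)


def _render(spec: PhantomSpec, geo: _Geometry, rng: np.random.Generator) -> np.ndarray:
    hc, wc = spec.canvas
    img = np.full((hc, wc), 0.08)

    _fill_poly(img, geo.sacrum_poly, 0.45)
    for body, (c_ia, c_ip, c_sa, c_sp) in geo.corners.items():
        _fill_poly(img, np.array([c_ia, c_ip, c_sp, c_sa]), _BONE)

    for fh in (geo.fem_left, geo.fem_right):
        rr, cc = disk((fh[1], fh[0]), geo.fem_radius, shape=img.shape)
        img[rr, cc] += 0.22

    px = 1.0 / geo.units_per_px  # px per abstract unit
    if spec.rib_occluders:
        for body in ("T2", "T4", "T6", "T8", "T10"):
            c = geo.centers[body]
            arc = np.array(
                [c + px * np.array([-0.2 - 1.3 * math.sin(a), 0.4 * math.cos(a)])
                 for a in np.linspace(0.2, 2.2, 12)]
            )
            _thick_line(img, arc, max(1.0, 0.05 * px), 0.18)
    if spec.shoulder_occluder:
        c7 = geo.centers["C7"]
        rr, cc = disk((c7[1] + 1.2 * px, c7[0] - 1.2 * px), 1.1 * px, shape=img.shape)
        img[rr, cc] += 0.18

    if spec.pathology == "scoliosis":
        # lateral projection of a coronal curve: ghost duplicates + contrast loss
        for body in ("T5", "T6", "T7", "T8", "T9"):
            c_ia, c_ip, c_sa, c_sp = geo.corners[body]
            off = np.array([0.18 * px, 0.10 * px])
            _fill_poly(img, np.array([c_ia, c_ip, c_sp, c_sa]) + off, 0.30, additive=True)

    if spec.pathology == "implant" and geo.rod_path is not None:
        _thick_line(img, geo.rod_path, max(1.5, 0.08 * px), _ROD)
        for p in geo.rod_path:  # pedicle screws
            _thick_line(img, np.array([p, p + np.array([0.45 * px, 0.0])]),
                        max(1.0, 0.05 * px), _ROD)

    if spec.pathology == "scoliosis":
        from scipy.ndimage import gaussian_filter

        t5, t9 = geo.centers["T5"], geo.centers["T9"]
        y0, y1 = int(max(0, t5[1] - px)), int(min(hc, t9[1] + px))
        img[y0:y1] = gaussian_filter(img[y0:y1], sigma=1.2)

    img = img + rng.normal(0.0, spec.noise, size=img.shape)
    img = img * (1.0 + 0.3 * spec.noise * rng.standard_normal(img.shape))
    return np.clip(img, 0.0, 1.0)


def generate_phantom(
    spec: PhantomSpec, return_geometry: bool = False
) -> tuple[RadiographImage, LandmarkSet] | tuple[RadiographImage, LandmarkSet, _Geometry]:
    """Render a phantom radiograph and its exact landmark set.

    Deterministic for a given spec (the seed drives tilt jitter and noise).
    Raises :class:`PhantomError` when the requested curvatures fold the
    spinal curve.
    """
    rng = np.random.default_rng(spec.seed)
    geo = _build_geometry(spec, rng)
    img = _render(spec, geo, rng)
    lm = LandmarkSet(
        {k: (float(v[0]), float(v[1])) for k, v in geo.landmarks.items()},
        pixel_spacing=spec.pixel_spacing,
        image_size=spec.canvas,
        anterior_direction=+1,
    )
    rad = RadiographImage(img, spec.pixel_spacing, source=f"phantom(seed={spec.seed})")
    return (rad, lm, geo) if return_geometry else (rad, lm)


def perturb_landmarks(lm: LandmarkSet, sd_px: float, seed: int = 0) -> LandmarkSet:
    """Isotropic Gaussian jitter of all 45 points (sd 0 returns the input
    unchanged); points are kept inside the image."""
    if sd_px < 0:
        raise ValueError("sd_px must be >= 0")
    if sd_px == 0:
        return lm
    rng = np.random.default_rng(seed)
    xy = lm.as_array() + rng.normal(0.0, sd_px, size=(45, 2))
    h, w = lm.image_size
    xy[:, 0] = np.clip(xy[:, 0], 0, w - 1e-6)
    xy[:, 1] = np.clip(xy[:, 1], 0, h - 1e-6)
    return lm.with_points(xy)


def simulate_observers(
    truth: "pd.DataFrame", noise_sds: dict[str, float] | list[float], seed: int = 0
):
    """Per-parameter rating matrices: truth + independent observer noise.

    ``truth`` is a subjects x parameters table; returns a dict mapping each
    parameter to a subjects x observers DataFrame (first column order
    follows ``noise_sds``).
    """
    import pandas as pd

    if not isinstance(noise_sds, dict):
        noise_sds = {f"obs{i + 1}": sd for i, sd in enumerate(noise_sds)}
    if len(noise_sds) < 2:
        raise ValueError("need at least two observers")
    rng = np.random.default_rng(seed)
    out = {}
    for param in truth.columns:
        base = truth[param].to_numpy(dtype=float)
        cols = {
            obs: base + rng.normal(0.0, sd, size=base.size)
            for obs, sd in noise_sds.items()
        }
        out[param] = pd.DataFrame(cols, index=truth.index)
    return out


def sample_spec(
    seed: int,
    pathology: str = "none",
    canvas: tuple[int, int] = (864, 480),
    pixel_spacing: float = 0.8,
) -> PhantomSpec:
    """Draw a random but class-conditioned phantom spec.

    Curvature distributions follow typical adult ranges (kyphosis class is
    drawn hyperkyphotic); values are clipped into the spec's plausible
    bounds.
    """
    rng = np.random.default_rng(seed)
    gtk_mu, gtk_sd = (55.0, 8.0) if pathology == "kyphosis" else (37.7, 10.0)
    draw = lambda mu, sd, lo, hi: float(np.clip(rng.normal(mu, sd), lo, hi))
    cl = draw(9.4, 8.0, -20, 35)
    gtk = draw(gtk_mu, gtk_sd, 12, 75)
    ll = draw(47.0, 12.0, 15, 75)
    pi = draw(51.6, 10.0, 30, 85)
    # keep the upper-thoracic tilt stackable: the realised T1 tilt is about
    # LL - 0.696*PI - GTK + 4, so couple the kyphosis draw to the
    # lumbopelvic draw (hyperkyphosis without lordosis cannot stand)
    anchor = ll - 0.696 * pi + 4.0
    gtk = float(np.clip(gtk, max(12.0, anchor - 66.0), min(75.0, anchor + 66.0)))
    return PhantomSpec(
        seed=seed,
        canvas=canvas,
        pixel_spacing=pixel_spacing,
        cervical_lordosis=cl,
        thoracic_kyphosis=gtk,
        lumbar_lordosis=ll,
        pelvic_incidence=pi,
        pathology=pathology,
    )


def make_dataset(
    n: int,
    seed: int = 0,
    canvas: tuple[int, int] = (864, 480),
    pixel_spacing: float = 0.8,
    class_weights: dict[str, float] | None = None,
) -> list[tuple[RadiographImage, LandmarkSet, PhantomSpec]]:
    """Generate ``n`` phantoms with the dataset's pathology class mix."""
    weights = class_weights or CLASS_WEIGHTS
    names = list(weights)
    probs = np.array([weights[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        pathology = str(rng.choice(names, p=probs))
        spec = sample_spec(int(rng.integers(2**31 - 1)), pathology, canvas, pixel_spacing)
        img, lm = generate_phantom(spec)
        out.append((img, lm, spec))
    return out


def mean_intervertebral_px(lm: LandmarkSet) -> float:
    """Mean distance between consecutive vertebral centres (px)."""
    pts = np.array([lm[c] for c in VERTEBRAL_CENTERS])
    return float(np.mean(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
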