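"""Deterministic spinopelvic parameter geometry.

Turns a 45-point :class:`~spinalign.schema.LandmarkSet` into the 18
radiographic parameters of sagittal balance: 5 fundamental (PI, SS, PT, LL,
SVA), 8 regional (CL, T1S, cSVA, GTK, PTK, MTK, L4SL, LPA) and 5 global
(SSA, GT, TPA, Barrey index, OD-HA).

Conventions (all centralised here so the wiring can be audited in one
place):

* image coordinates: x = column, y = row, y increases downward, cranial is
  -y; the patient's front is ``anterior_direction`` (+x by default);
* lordosis positive, kyphosis positive;
* offset parameters (SVA, cSVA, OD-HA, the Barrey numerator) are
  anterior-positive; SVA/cSVA are in mm, angles in degrees;
* slope-type parameters (SS, T1S) are positive when the anterior end of the
  endplate is caudal to the posterior end (the usual clinical reading);
* the hip axis is the midpoint of the two femoral-head centres; the C7 plumb
  line drops from CENTER_C7, the dens plumb from C2_DENS_CENTER; SVA is
  referenced to the posterior sacral-endplate edge;
* angles come from two-argument arctangents; no small-angle approximations.

With these conventions the decomposition ``PI = PT + SS`` holds exactly at
the sacral-endplate midpoint for any valid landmark configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .schema import LandmarkID as L
from .schema import LandmarkSet


class GeometryError(ValueError):
    """Degenerate landmark configuration (zero-length line etc.)."""


@dataclass(frozen=True)
class Line2D:
    """A directed segment between two distinct points (pixel coordinates)."""

    p: tuple[float, float]
    q: tuple[float, float]

    def __post_init__(self) -> None:
        if self.p == self.q:
            raise GeometryError(f"zero-length line at {self.p}")

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.q, dtype=float) - np.asarray(self.p, dtype=float)


@dataclass(frozen=True)
class SpinopelvicParameters:
    """The 18 derived parameters. Angles in degrees, SVA/cSVA in mm,
    barrey_index dimensionless."""

    PI: float
    SS: float
    PT: float
    LL: float
    SVA: float
    CL: float
    T1S: float
    cSVA: float
    GTK: float
    PTK: float
    MTK: float
    L4SL: float
    LPA: float
    SSA: float
    GT: float
    TPA: float
    barrey_index: float
    OD_HA: float

    UNITS = {"SVA": "mm", "cSVA": "mm", "barrey_index": "ratio"}

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise GeometryError(f"non-finite parameter {f.name} = {v}")
            if f.name not in self.UNITS and not (-180.0 < v <= 180.0):
                raise GeometryError(f"{f.name} = {v} outside (-180, 180]")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @staticmethod
    def names() -> list[str]:
        return [f.name for f in fields(SpinopelvicParameters)]

    @staticmethod
    def unit(name: str) -> str:
        return SpinopelvicParameters.UNITS.get(name, "deg")


def _wrap(deg: float) -> float:
    """Map an angle to (-180, 180]."""
    out = deg - 360.0 * math.floor((deg + 180.0) / 360.0)
    return 180.0 if out <= -180.0 else out


# --- angle primitives ------------------------------------------------------


def angle_to_horizontal(line: Line2D, anterior_direction: int = +1) -> float:
    """Signed tilt of a line in (-90, 90]: 0 when horizontal, positive when
    the anterior end is cranial to the posterior end."""
    v = line.vector
    ant, u = v[0] * anterior_direction, -v[1]
    if ant < 0 or (ant == 0 and u < 0):
        ant, u = -ant, -u
    if ant == 0:
        return 90.0
    return math.degrees(math.atan2(u, ant))


def angle_between(line_a: Line2D, line_b: Line2D) -> float:
    """Signed angle of B's direction relative to A's, in (-180, 180];
    antisymmetric in its arguments."""
    a, b = line_a.vector, line_b.vector
    ang = math.degrees(math.atan2(a[0] * b[1] - a[1] * b[0], a @ b))
    return _wrap(ang)


def _from_down(v: np.ndarray, a: int) -> float:
    """Anterior-signed angle of ``v`` from the downward vertical (deg)."""
    if not np.any(v):
        raise GeometryError("zero-length direction")
    return math.degrees(math.atan2(v[0] * a, v[1]))


def _from_up(v: np.ndarray, a: int) -> float:
    """Anterior-signed angle of ``v`` from the upward vertical (deg)."""
    if not np.any(v):
        raise GeometryError("zero-length direction")
    return math.degrees(math.atan2(v[0] * a, -v[1]))


# --- wiring helpers --------------------------------------------------------


def _pt(lm: LandmarkSet, key: L) -> np.ndarray:
    return np.asarray(lm[key], dtype=float)


def _mid(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return (p + q) / 2.0


def _endplate_tilt(lm: LandmarkSet, anterior: L, posterior: L) -> float:
    """angle_to_horizontal of an endplate given its anterior/posterior points."""
    return angle_to_horizontal(
        Line2D(tuple(_pt(lm, posterior)), tuple(_pt(lm, anterior))),
        lm.anterior_direction,
    )


def _sacral_frame(lm: LandmarkSet) -> tuple[np.ndarray, np.ndarray, float]:
    """Sacral midpoint, hip-axis midpoint and SS (deg)."""
    s1a, s1p = _pt(lm, L.S1_ANTERIOR_EDGE), _pt(lm, L.S1_POSTERIOR_EDGE)
    if np.array_equal(s1a, s1p):
        raise GeometryError("degenerate sacral endplate (coincident edges)")
    fl, fr = _pt(lm, L.FEMORAL_HEAD_LEFT_CENTER), _pt(lm, L.FEMORAL_HEAD_RIGHT_CENTER)
    if np.array_equal(fl, fr):
        raise GeometryError("coincident femoral-head centres: hip axis undefined")
    m = _mid(s1a, s1p)
    h = _mid(fl, fr)
    ss = -_caudal_normal_angle(s1a - s1p, lm.anterior_direction)
    return m, h, ss


def _caudal_normal_angle(endplate_vec: np.ndarray, a: int) -> float:
    """Anterior-signed from-down angle of the caudally pointing endplate
    normal."""
    n = np.array([-endplate_vec[1], endplate_vec[0]])  # one perpendicular
    if n[1] < 0 or (n[1] == 0 and n[0] * a < 0):
        n = -n  # choose the branch pointing downward (caudal)
    return _from_down(n, a)


# --- parameter groups ------------------------------------------------------


def compute_fundamental(lm: LandmarkSet) -> tuple[float, float, float, float, float]:
    """(PI, SS, PT, LL, SVA): the five fundamental spinopelvic parameters."""
    a = lm.anterior_direction
    m, h, ss = _sacral_frame(lm)
    if np.array_equal(h, m):
        raise GeometryError("hip axis coincides with sacral midpoint")
    pt = _from_down(h - m, a)
    pi = _wrap(pt + ss)  # directed angle from the caudal endplate normal to M->H
    theta_l1 = _endplate_tilt(lm, L.L1_ANTEROSUPERIOR, L.L1_POSTEROSUPERIOR)
    ll = _wrap(theta_l1 + ss)  # = tilt(L1 sup) - tilt(sacral endplate)
    sva = (
        (_pt(lm, L.CENTER_C7)[0] - _pt(lm, L.S1_POSTERIOR_EDGE)[0])
        * a
        * lm.pixel_spacing
    )
    return pi, ss, pt, ll, sva


def compute_regional(
    lm: LandmarkSet,
) -> tuple[float, float, float, float, float, float, float, float]:
    """(CL, T1S, cSVA, GTK, PTK, MTK, L4SL, LPA): regional spinal parameters."""
    a = lm.anterior_direction
    t_c2i = _endplate_tilt(lm, L.C2_ANTEROINFERIOR, L.C2_POSTEROINFERIOR)
    t_c7i = _endplate_tilt(lm, L.C7_ANTEROINFERIOR, L.C7_POSTEROINFERIOR)
    t_t1s = _endplate_tilt(lm, L.T1_ANTEROSUPERIOR, L.T1_POSTEROSUPERIOR)
    t_t5s = _endplate_tilt(lm, L.T5_ANTEROSUPERIOR, L.T5_POSTEROSUPERIOR)
    t_t5i = _endplate_tilt(lm, L.T5_ANTEROINFERIOR, L.T5_POSTEROINFERIOR)
    t_t12i = _endplate_tilt(lm, L.T12_ANTEROINFERIOR, L.T12_POSTEROINFERIOR)
    t_l4s = _endplate_tilt(lm, L.L4_ANTEROSUPERIOR, L.L4_POSTEROSUPERIOR)
    m, h, ss = _sacral_frame(lm)

    cl = _wrap(t_c2i - t_c7i)
    t1s = -t_t1s
    csva = (
        (_pt(lm, L.C2_DENS_CENTER)[0] - _pt(lm, L.C7_POSTEROSUPERIOR)[0])
        * a
        * lm.pixel_spacing
    )
    gtk = _wrap(t_t12i - t_t1s)
    ptk = _wrap(t_t5i - t_t1s)
    mtk = _wrap(t_t12i - t_t5s)
    l4sl = _wrap(t_l4s + ss)
    lpa = _wrap(_from_up(_pt(lm, L.CENTER_L1) - h, a) - _from_up(m - h, a))
    return cl, t1s, csva, gtk, ptk, mtk, l4sl, lpa


def compute_global(lm: LandmarkSet) -> tuple[float, float, float, float, float]:
    """(SSA, GT, TPA, barrey_index, OD_HA): global spinopelvic parameters."""
    a = lm.anterior_direction
    m, h, ss = _sacral_frame(lm)
    c7 = _pt(lm, L.CENTER_C7)
    dens = _pt(lm, L.C2_DENS_CENTER)
    s1p = _pt(lm, L.S1_POSTERIOR_EDGE)

    beta = _from_up(c7 - m, a)  # C7 tilt at the sacral midpoint
    ssa = _wrap(90.0 + ss - beta)  # sacral endplate line vs the M->C7 ray
    pt = _from_down(h - m, a)
    gt = _wrap(pt - _from_down(m - c7, a))  # equals PT + beta
    tpa = _wrap(_from_up(_pt(lm, L.CENTER_T1) - h, a) - _from_up(m - h, a))
    sfd = (h[0] - s1p[0]) * a  # anterior-signed sacrofemoral offset (px)
    if sfd == 0:
        raise GeometryError("zero sacrofemoral horizontal distance: Barrey index undefined")
    barrey = ((c7[0] - h[0]) * a) / sfd
    od_ha = _from_up(dens - h, a)
    return ssa, gt, tpa, barrey, od_ha


def compute_all(lm: LandmarkSet) -> SpinopelvicParameters:
    """All 18 parameters from one landmark set."""
    pi, ss, pt, ll, sva = compute_fundamental(lm)
    cl, t1s, csva, gtk, ptk, mtk, l4sl, lpa = compute_regional(lm)
    ssa, gt, tpa, barrey, od_ha = compute_global(lm)
    return SpinopelvicParameters(
        PI=pi, SS=ss, PT=pt, LL=ll, SVA=sva,
        CL=cl, T1S=t1s, cSVA=csva, GTK=gtk, PTK=ptk, MTK=mtk, L4SL=l4sl, LPA=lpa,
        SSA=ssa, GT=gt, TPA=tpa, barrey_index=barrey, OD_HA=od_ha,
    )
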