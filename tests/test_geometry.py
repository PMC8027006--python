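"""Spinopelvic parameter geometry: primitives, wiring and invariances."""

import math

import numpy as np
import pytest

from spinalign.geometry import (
    GeometryError,
    Line2D,
    angle_between,
    angle_to_horizontal,
    compute_all,
    compute_fundamental,
    compute_global,
    compute_regional,
)
from spinalign.schema import LandmarkID as L

from conftest import build_canonical, rotate_landmarks, translate_landmarks

SHAPE_ANGLES = ["PI", "LL", "CL", "GTK", "PTK", "MTK", "L4SL", "SSA", "GT", "TPA", "LPA"]
GRAVITY_ANGLES = ["T1S", "SS", "PT", "OD_HA"]


class TestPrimitives:
    def test_horizontal_line_has_zero_tilt(self):
        assert angle_to_horizontal(Line2D((0, 100), (40, 100))) == 0.0

    def test_anterior_end_cranial_is_positive(self):
        # anterior (+x) end 40 px higher: +45 degrees
        assert angle_to_horizontal(Line2D((0, 100), (40, 60))) == pytest.approx(45.0)

    def test_rotation_shifts_tilt_by_the_rotation_angle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p, q = rng.uniform(-50, 50, (2, 2))
            if np.allclose(p, q):
                continue
            base = angle_to_horizontal(Line2D(tuple(p), tuple(q)))
            if abs(base) > 75:  # stay away from the +/-90 wrap
                continue
            t = math.radians(10.0)
            # image coords y-down: this matrix tilts the anterior end cranially
            rot = np.array([[math.cos(t), math.sin(t)], [-math.sin(t), math.cos(t)]])
            rotated = angle_to_horizontal(Line2D(tuple(rot @ p), tuple(rot @ q)))
            assert rotated == pytest.approx(base + 10.0, abs=1e-9)

    def test_zero_length_line_rejected(self):
        with pytest.raises(GeometryError):
            Line2D((3, 4), (3, 4))

    def test_angle_between_identity_and_quarter_turn(self):
        a = Line2D((0, 0), (10, 0))
        b = Line2D((5, 5), (5, 25))
        assert angle_between(a, a) == 0.0
        assert abs(angle_between(a, b)) == pytest.approx(90.0)

    def test_angle_between_is_antisymmetric_and_additive(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            lines = [
                Line2D(tuple(p), tuple(q))
                for p, q in rng.uniform(-10, 10, (3, 2, 2))
                if not np.allclose(p, q)
            ]
            if len(lines) < 3:
                continue
            a, b, c = lines
            assert angle_between(a, b) == pytest.approx(-angle_between(b, a), abs=1e-9)
            total = angle_between(a, b) + angle_between(b, c) - angle_between(a, c)
            assert min(abs(total), abs(abs(total) - 360.0)) < 1e-9


class TestFundamental:
    def test_neutral_configuration_zeroes_pelvic_angles(self):
        pi, ss, pt, ll, sva = compute_fundamental(build_canonical())
        assert ss == pytest.approx(0.0, abs=1e-9)
        assert pt == pytest.approx(0.0, abs=1e-9)
        assert pi == pytest.approx(0.0, abs=1e-9)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_tilted_sacrum_with_vertical_hip_line(self):
        # anterior sacral edge caudal by 30 deg, hips straight below the midpoint
        d = 20.0 * math.tan(math.radians(30.0))
        lm = build_canonical(
            S1_ANTERIOR_EDGE=(270.0, 730.0 + d),
            S1_POSTERIOR_EDGE=(230.0, 730.0 - d),
        )
        pi, ss, pt, ll, _ = compute_fundamental(lm)
        assert ss == pytest.approx(30.0, abs=1e-9)
        assert pt == pytest.approx(0.0, abs=1e-9)
        assert pi == pytest.approx(30.0, abs=1e-9)

    def test_sva_is_anterior_signed_mm(self):
        lm = build_canonical(CENTER_C7=(150.0, 250.0), S1_POSTERIOR_EDGE=(130.0, 730.0))
        *_, sva = compute_fundamental(lm)
        assert sva == pytest.approx((150 - 130) * 0.5)  # +10 mm

    def test_pi_decomposition_on_random_valid_sets(self, random_landmark_sets):
        for lm in random_landmark_sets:
            pi, ss, pt, *_ = compute_fundamental(lm)
            assert abs(pi - (pt + ss)) < 1e-6

    def test_coincident_femoral_heads_rejected(self):
        lm = build_canonical(
            FEMORAL_HEAD_LEFT_CENTER=(250.0, 800.0),
            FEMORAL_HEAD_RIGHT_CENTER=(250.0, 800.0),
        )
        with pytest.raises(GeometryError, match="femoral"):
            compute_fundamental(lm)


class TestRegional:
    def test_all_horizontal_endplates_zero_the_angles(self):
        cl, t1s, csva, gtk, ptk, mtk, l4sl, lpa = compute_regional(build_canonical())
        for v in (cl, t1s, gtk, ptk, mtk, l4sl, lpa):
            assert v == pytest.approx(0.0, abs=1e-9)
        assert csva == pytest.approx((250 - 240) * 0.5)  # dens vs C7 posterosuperior

    def test_csva_example(self):
        lm = build_canonical(
            C2_DENS_CENTER=(140.0, 95.0), C7_POSTEROSUPERIOR=(120.0, 237.0), spacing=0.25
        )
        csva = compute_regional(lm)[2]
        assert csva == pytest.approx(5.0)

    def test_gtk_splits_into_ptk_plus_mtk_when_t5_plates_parallel(self):
        # tilt T1 sup by -10, T12 inf by +12, T5 plates both by +4
        def plate(y, tilt):
            d = 20.0 * math.tan(math.radians(tilt))
            return {"a": (270.0, y - d), "p": (230.0, y + d)}

        t1 = plate(276.0, -10.0)
        t5s = plate(367.0, 4.0)
        t5i = plate(393.0, 4.0)
        t12 = plate(575.0, 12.0)
        lm = build_canonical(
            T1_ANTEROSUPERIOR=t1["a"], T1_POSTEROSUPERIOR=t1["p"],
            T5_ANTEROSUPERIOR=t5s["a"], T5_POSTEROSUPERIOR=t5s["p"],
            T5_ANTEROINFERIOR=t5i["a"], T5_POSTEROINFERIOR=t5i["p"],
            T12_ANTEROINFERIOR=t12["a"], T12_POSTEROINFERIOR=t12["p"],
        )
        _, _, _, gtk, ptk, mtk, _, _ = compute_regional(lm)
        assert gtk == pytest.approx(ptk + mtk, abs=1e-9)
        assert gtk == pytest.approx(22.0, abs=1e-9)


class TestGlobal:
    def test_dens_above_hip_axis_zeroes_od_ha(self):
        od_ha = compute_global(build_canonical())[4]
        assert od_ha == pytest.approx(0.0, abs=1e-9)

    def test_c7_on_hip_vertical_zeroes_barrey(self):
        lm = build_canonical()  # C7 centre and hip axis share x = 250
        barrey = compute_global(lm)[3]
        assert barrey == 0.0

    def test_zero_sacrofemoral_distance_is_an_error(self):
        lm = build_canonical(S1_POSTERIOR_EDGE=(250.0, 730.0))
        with pytest.raises(GeometryError, match="Barrey"):
            compute_global(lm)

    def test_gt_equals_pt_plus_c7_tilt(self, random_landmark_sets):
        # angle-addition oracle at the sacral midpoint
        for lm in random_landmark_sets:
            _, _, pt, *_ = compute_fundamental(lm)
            gt = compute_global(lm)[1]
            m = (np.array(lm[L.S1_ANTERIOR_EDGE]) + np.array(lm[L.S1_POSTERIOR_EDGE])) / 2
            c7 = np.array(lm[L.CENTER_C7])
            v = c7 - m
            beta = math.degrees(math.atan2(v[0], -v[1]))
            assert gt == pytest.approx(pt + beta, abs=1e-9)


class TestInvariances:
    def test_translation_leaves_all_parameters_unchanged(self, random_landmark_sets):
        for lm in random_landmark_sets[:8]:
            base = compute_all(lm).as_dict()
            moved = compute_all(translate_landmarks(lm, 37.25, -21.5)).as_dict()
            for name, v in base.items():
                assert moved[name] == pytest.approx(v, abs=1e-9), name

    def test_rotation_equivariance_split(self, random_landmark_sets):
        theta = 7.0
        for lm in random_landmark_sets[:8]:
            base = compute_all(lm).as_dict()
            rot = compute_all(rotate_landmarks(lm, theta)).as_dict()
            for name in SHAPE_ANGLES:
                assert rot[name] == pytest.approx(base[name], abs=1e-7), name
            # gravity-referenced parameters shift by the rotation angle:
            # PT (down-going hip ray) one way; SS, T1S and OD-HA (slopes and
            # up-going rays, anterior-positive) the other, so PI = PT + SS
            # stays invariant
            d_pt = rot["PT"] - base["PT"]
            assert abs(d_pt) == pytest.approx(theta, abs=1e-7)
            assert rot["OD_HA"] - base["OD_HA"] == pytest.approx(-d_pt, abs=1e-7)
            assert rot["SS"] - base["SS"] == pytest.approx(-d_pt, abs=1e-7)
            assert rot["T1S"] - base["T1S"] == pytest.approx(-d_pt, abs=1e-7)

    def test_rescaling_px_and_spacing_leaves_parameters_unchanged(self, random_landmark_sets):
        from spinalign.schema import LandmarkSet

        for lm in random_landmark_sets[:6]:
            base = compute_all(lm).as_dict()
            f = 3.0
            scaled = LandmarkSet.from_array(
                lm.as_array() * f,
                lm.pixel_spacing / f,
                (lm.image_size[0] * 3, lm.image_size[1] * 3),
                lm.anterior_direction,
            )
            out = compute_all(scaled).as_dict()
            for name, v in base.items():
                assert out[name] == pytest.approx(v, abs=1e-8), name

    def test_barrey_index_ignores_pixel_spacing(self):
        from spinalign.schema import LandmarkSet

        lm = build_canonical(CENTER_C7=(260.0, 250.0))
        b1 = compute_global(lm)[3]
        lm2 = LandmarkSet(lm.points, lm.pixel_spacing * 10, lm.image_size)
        assert compute_global(lm2)[3] == b1

    def test_compute_all_returns_18_finite_values(self, random_landmark_sets):
        params = compute_all(random_landmark_sets[0])
        values = params.as_dict()
        assert len(values) == 18
        assert all(np.isfinite(v) for v in values.values())
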