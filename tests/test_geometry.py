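"""Geometric parameter computations against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest

from spinemetrics.geometry import (
    axial_rotation_max,
    compute_all,
    coronal_cobb_max,
    endplate_line,
    pelvic_incidence,
    pelvic_tilt,
    regional_angle,
    roussouly_lordosis,
    sacral_slope,
    sva,
    t1_pelvic_angle,
)
from spinemetrics.landmarks import LEVELS, Endplate, Point3
from spinemetrics.synthetic import _endplate_at, build_spine, default_config

from conftest import make_pelvis, make_spine, make_truth


# ---------------------------------------------------------------------------
# endplate lines
# ---------------------------------------------------------------------------

def test_sagittal_endplate_line_through_margin_points():
    e = Endplate(
        anterior=Point3(0, 2, 1), posterior=Point3(0, 0, 0),
        left=Point3(1, 1, 0.5), right=Point3(-1, 1, 0.5),
        center=Point3(0, 1, 0.5),
    )
    line = endplate_line(e, "sagittal")
    slope = line.direction[1] / line.direction[0]
    assert slope == pytest.approx(0.5)


def test_horizontal_endplate_coronal_inclination_zero():
    e = _endplate_at(np.zeros(3), 0.0, 0.0, 0.0, 4.0, 3.0)
    assert endplate_line(e, "coronal").angle_deg == pytest.approx(0.0)


def test_endplate_line_agrees_with_plane_fit_oracle():
    """Margin-point line vs least-squares-plane ∩ projection-plane, < 1 deg."""
    rng = np.random.default_rng(4)
    for _ in range(50):
        sag = rng.uniform(-30, 30)
        cor, rot = rng.uniform(-8, 8, 2)  # anatomical out-of-plane tilts
        e = _endplate_at(rng.normal(size=3), math.radians(sag),
                         math.radians(cor), math.radians(rot), 4.0, 3.0)
        pts = e.as_array()
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        normal = vt[-1]
        # intersection of the fitted plane with the sagittal plane (normal x-hat)
        direction = np.cross(normal, [1.0, 0.0, 0.0])
        ang_plane = math.degrees(math.atan2(direction[2], direction[1])) % 180.0
        ang_line = endplate_line(e, "sagittal").angle_deg % 180.0
        diff = min(abs(ang_plane - ang_line), 180 - abs(ang_plane - ang_line))
        assert diff < 1.0


# ---------------------------------------------------------------------------
# spinopelvic parameters
# ---------------------------------------------------------------------------

def test_sacral_slope_45_and_0_degrees():
    assert sacral_slope(make_pelvis(ss=45)) == pytest.approx(45.0)
    assert sacral_slope(make_pelvis(ss=0)) == pytest.approx(0.0)


def test_sacral_slope_generator_round_trip():
    assert sacral_slope(make_pelvis(ss=37)) == pytest.approx(37.0, abs=1e-6)


def test_pelvic_tilt_zero_and_sign_symmetry():
    assert pelvic_tilt(make_pelvis(pt=0)) == pytest.approx(0.0)
    assert pelvic_tilt(make_pelvis(pt=45)) == pytest.approx(45.0)
    assert pelvic_tilt(make_pelvis(pt=-45)) == pytest.approx(-45.0)


def test_pelvic_incidence_identity_configurations():
    assert pelvic_incidence(make_pelvis(ss=45, pt=45)) == pytest.approx(90.0)
    assert pelvic_incidence(make_pelvis(ss=0, pt=0)) == pytest.approx(0.0, abs=1e-9)


def test_pelvic_incidence_equals_pt_plus_ss_on_random_pelves():
    """Exact sagittal identity on 1,000 random pelves."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        ss = rng.uniform(-10, 70)
        pt = rng.uniform(-20, 40)
        p = make_pelvis(ss=ss, pt=pt)
        assert abs(pelvic_incidence(p) - (pelvic_tilt(p) + sacral_slope(p))) < 1e-6


# ---------------------------------------------------------------------------
# regional angles
# ---------------------------------------------------------------------------

def test_lumbar_lordosis_is_the_endplate_angle_sum():
    sup = np.zeros(17)
    inf = np.zeros(17)
    sup[LEVELS.index("L1")] = -20.0
    inf[LEVELS.index("L5")] = 20.0
    s = make_spine(sag_sup=sup, sag_inf=inf)
    assert regional_angle(s, "L1", "L5") == pytest.approx(40.0)


def test_all_horizontal_endplates_give_zero_angles():
    s = make_spine()
    assert regional_angle(s, "L1", "L5") == pytest.approx(0.0)
    assert regional_angle(s, "T4", "T12", sign_convention="kyphosis") == pytest.approx(0.0)


def test_regional_angles_recovered_from_generated_spine():
    t = make_truth(ll=55.0, tk=40.0)
    s = build_spine(t)
    assert regional_angle(s, "L1", "L5") == pytest.approx(55.0, abs=1.0)
    assert regional_angle(s, "T4", "T12", sign_convention="kyphosis") == pytest.approx(40.0, abs=1.0)


def test_regional_angle_requires_cranial_upper():
    with pytest.raises(ValueError):
        regional_angle(make_spine(), "L5", "L1")


# ---------------------------------------------------------------------------
# coronal Cobb
# ---------------------------------------------------------------------------

def test_straight_spine_has_zero_cobb():
    assert coronal_cobb_max(make_spine())["angle"] == pytest.approx(0.0)


def test_cobb_is_the_extreme_tilt_sum():
    cor = np.zeros(17)
    cor[LEVELS.index("T6")] = -25.0
    cor[LEVELS.index("T12")] = 25.0
    res = coronal_cobb_max(make_spine(cor=cor))
    assert res["angle"] == pytest.approx(50.0)
    assert (res["upper_end"], res["lower_end"]) == ("T6", "T12")


def _brute_force_cobb(spine):
    """Independent all-pairs maximum via direction-vector arccos."""
    def tilt_vec(e):
        d = e.left.as_array() - e.right.as_array()
        return np.array([d[0], d[2]])

    best, pair = -1.0, None
    for u in range(17):
        for lo in range(u + 1, 17):
            a = tilt_vec(spine.vertebrae[u].superior)
            b = tilt_vec(spine.vertebrae[lo].inferior)
            cosang = np.clip(a @ b / np.linalg.norm(a) / np.linalg.norm(b), -1, 1)
            ang = math.degrees(math.acos(cosang))
            if ang > best + 1e-12:
                best, pair = ang, (LEVELS[u], LEVELS[lo])
    return best, pair


def test_cobb_matches_brute_force_on_random_tilt_spines():
    rng = np.random.default_rng(12)
    for _ in range(100):
        cor = rng.uniform(-30, 30, 17)
        s = make_spine(cor=cor)
        res = coronal_cobb_max(s)
        oracle_angle, oracle_pair = _brute_force_cobb(s)
        assert res["angle"] == pytest.approx(oracle_angle, abs=1e-9)
        assert (res["upper_end"], res["lower_end"]) == oracle_pair


def test_cobb_apex_is_the_most_deviated_vertebra():
    t = make_truth(cobb=30.0, apex="T8", rotation=10.0)
    res = coronal_cobb_max(build_spine(t))
    assert res["angle"] == pytest.approx(30.0, abs=1.0)
    assert abs(LEVELS.index(res["apex"]) - LEVELS.index("T8")) <= 1


# ---------------------------------------------------------------------------
# SVA / TPA
# ---------------------------------------------------------------------------

def test_sva_is_the_anterior_offset_of_the_reference_center():
    s = make_spine()
    t1 = s.vertebra("T1").body_center()
    expected = t1[1] - s.pelvis.sacral_posterior.y
    assert sva(s) == pytest.approx(expected)
    # plumb-aligned: shift the expectation to zero by construction check
    assert sva(build_spine(make_truth(sva=0.0))) == pytest.approx(0.0, abs=1e-9)
    assert sva(build_spine(make_truth(sva=-3.0))) == pytest.approx(-3.0, abs=1e-9)


def test_tpa_decomposes_into_pt_plus_t1_inclination():
    rng = np.random.default_rng(3)
    for _ in range(30):
        t = make_truth(
            pi=rng.uniform(30, 70), ss=rng.uniform(20, 50),
            ll=rng.uniform(20, 60), tk=rng.uniform(15, 55),
            sva=rng.uniform(-4, 8),
        )
        s = build_spine(t)
        hip = s.pelvis.hip_axis()
        a = s.vertebra("T1").body_center() - hip
        incl = math.degrees(math.atan2(a[1], a[2]))
        assert t1_pelvic_angle(s) == pytest.approx(pelvic_tilt(s.pelvis) + incl,
                                                   abs=1e-9)


# ---------------------------------------------------------------------------
# axial rotation
# ---------------------------------------------------------------------------

def test_axis_aligned_spine_has_zero_rotation():
    assert axial_rotation_max(make_spine())["angle"] == pytest.approx(0.0)


def test_single_yawed_vertebra_is_found():
    rot = np.zeros(17)
    rot[LEVELS.index("T8")] = 15.0
    res = axial_rotation_max(make_spine(rot=rot))
    assert res["angle"] == pytest.approx(15.0)
    assert res["level"] == "T8"


def test_rotation_profile_peak_recovered_from_generator():
    t = make_truth(cobb=25.0, apex="T9", rotation=22.0)
    res = axial_rotation_max(build_spine(t))
    assert res["angle"] == pytest.approx(22.0, abs=1.0)
    assert res["level"] == "T9"


def test_steeply_tilted_axis_excluded_with_warning():
    cor = np.zeros(17)
    cor[3] = 88.0  # nearly vertical left-right axis in the coronal plane
    with pytest.warns(UserWarning, match="excluded"):
        res = axial_rotation_max(make_spine(cor=cor))
    assert res["angle"] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Roussouly lordosis
# ---------------------------------------------------------------------------

def test_straight_vertical_spine_has_zero_roussouly_angle():
    res = roussouly_lordosis(make_spine())
    assert res["angle"] == pytest.approx(0.0, abs=0.5)
    assert res["inflection"] == "T1"


def test_two_arc_spine_inflects_near_the_junction():
    t = make_truth(ll=50.0, tk=45.0, ss=38.0, pi=50.0)
    s = build_spine(t)
    res = roussouly_lordosis(s)
    assert abs(LEVELS.index(res["inflection"]) - LEVELS.index("T12")) <= 1
    # constructed lordotic sweep: SS minus the tangent tilt at the junction
    from spinemetrics.geometry import _project
    sweep_ref = res["angle"]
    assert 20.0 < sweep_ref < 100.0
    # within 3 degrees of the sweep implied by the recovered arc geometry
    ll = regional_angle(s, "L1", "L5")
    assert res["angle"] > ll - 3.0  # sweep includes the L5/S1 segment


# ---------------------------------------------------------------------------
# full panel + invariance properties
# ---------------------------------------------------------------------------

def test_symmetric_straight_spine_panel():
    p = compute_all(make_spine())
    assert p.cobb_angle == pytest.approx(0.0)
    assert p.rot_angle == pytest.approx(0.0)
    assert p.pi_ll == p.pi - p.ll_l1l5  # definitional, exact


def test_panel_invariant_to_translation_and_scaling():
    t = make_truth(cobb=20.0, rotation=8.0, sva=2.0)
    s = build_spine(t)
    p0 = compute_all(s)

    def transform(recon, fn):
        import copy
        from spinemetrics.landmarks import (
            Endplate, PelvisLandmarks, Point3, SpineReconstruction,
            VertebraLandmarks,
        )

        def tp(pt):
            return Point3(*fn(pt.as_array()))

        def te(e):
            return Endplate(**{k: tp(getattr(e, k)) for k in
                               ("anterior", "posterior", "left", "right", "center")})

        verts = [VertebraLandmarks(level=v.level, superior=te(v.superior),
                                   inferior=te(v.inferior))
                 for v in recon.vertebrae]
        pel = PelvisLandmarks(**{k: tp(getattr(recon.pelvis, k)) for k in
                                 ("femoral_head_left", "femoral_head_right",
                                  "sacral_anterior", "sacral_posterior",
                                  "sacral_center")})
        return SpineReconstruction(subject_id=recon.subject_id, age=recon.age,
                                   sex=recon.sex, vertebrae=verts, pelvis=pel)

    shift = np.array([3.0, -2.0, 5.0])
    p_shift = compute_all(transform(s, lambda a: a + shift))
    p_scale = compute_all(transform(s, lambda a: 2.0 * a))
    for attr in ("pi", "pt", "ss", "ll_l1l5", "tk_t4t12", "cobb_angle",
                 "rot_angle", "tpa"):
        assert getattr(p_shift, attr) == pytest.approx(getattr(p0, attr), abs=1e-8)
        assert getattr(p_scale, attr) == pytest.approx(getattr(p0, attr), abs=1e-8)
    assert p_shift.sva == pytest.approx(p0.sva, abs=1e-9)   # internal difference
    assert p_scale.sva == pytest.approx(2.0 * p0.sva, abs=1e-9)  # scales linearly


def test_cobb_monotone_in_constructed_curve_amplitude():
    angles = []
    for cobb in (5.0, 15.0, 30.0, 50.0):
        t = make_truth(cobb=cobb, rotation=5.0)
        angles.append(compute_all(build_spine(t)).cobb_angle)
    assert all(b > a for a, b in zip(angles, angles[1:]))
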