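"""Shared fixtures: hand-buildable spines and small synthetic cohorts."""

from __future__ import annotations

import math

import numpy as np
import pytest

from spinemetrics.landmarks import (
    LEVELS,
    PelvisLandmarks,
    Point3,
    SpineReconstruction,
    VertebraLandmarks,
)
from spinemetrics.synthetic import (
    GeneratorConfig,
    TruthRecord,
    _endplate_at,
    default_config,
)

_DEG = math.pi / 180.0


def make_pelvis(ss: float = 0.0, pt: float = 0.0, depth: float = 5.0,
                hip_offset: float = 7.0, span: float = 17.5) -> PelvisLandmarks:
    """Pelvis realizing the given sacral slope and pelvic tilt (degrees)."""
    ss_r, pt_r = ss * _DEG, pt * _DEG
    sc = np.zeros(3)
    plate = np.array([0.0, math.cos(ss_r), -math.sin(ss_r)])
    hip = sc + hip_offset * np.array([0.0, math.sin(pt_r), -math.cos(pt_r)])
    return PelvisLandmarks(
        femoral_head_left=Point3(*(hip + [span / 2, 0, 0])),
        femoral_head_right=Point3(*(hip - [span / 2, 0, 0])),
        sacral_anterior=Point3(*(sc + depth / 2 * plate)),
        sacral_posterior=Point3(*(sc - depth / 2 * plate)),
        sacral_center=Point3(*sc),
    )


def make_spine(
    sag_sup=None, sag_inf=None, cor=None, rot=None, lat=None,
    ss: float = 0.0, pt: float = 0.0,
    subject_id: str = "T", age: float = 30.0, sex: str = "F",
) -> SpineReconstruction:
    """Stacked-vertebra spine with per-level endplate tilts (degrees).

    Vertebrae are stacked vertically above a simple pelvis; each argument is
    a 17-vector (T1→L5 order) of sagittal superior/inferior tilts, coronal
    tilts, axial rotations and lateral offsets (cm).  Defaults are zero, i.e.
    a straight vertical spine with horizontal endplates.
    """
    n = len(LEVELS)
    zeros = np.zeros(n)
    sag_sup = zeros if sag_sup is None else np.asarray(sag_sup, float)
    sag_inf = zeros if sag_inf is None else np.asarray(sag_inf, float)
    cor = zeros if cor is None else np.asarray(cor, float)
    rot = zeros if rot is None else np.asarray(rot, float)
    lat = zeros if lat is None else np.asarray(lat, float)
    vertebrae = []
    z_top = 3.0 * n + 2.0  # T1 superior endplate height above the pelvis
    for i, lvl in enumerate(LEVELS):
        z_sup = z_top - 3.0 * i
        center_sup = np.array([lat[i], 0.0, z_sup])
        center_inf = np.array([lat[i], 0.0, z_sup - 2.0])
        vertebrae.append(
            VertebraLandmarks(
                level=lvl,
                superior=_endplate_at(center_sup, sag_sup[i] * _DEG,
                                      cor[i] * _DEG, rot[i] * _DEG, 4.0, 3.0),
                inferior=_endplate_at(center_inf, sag_inf[i] * _DEG,
                                      cor[i] * _DEG, rot[i] * _DEG, 4.0, 3.0),
            )
        )
    return SpineReconstruction(
        subject_id=subject_id, age=age, sex=sex,
        vertebrae=vertebrae, pelvis=make_pelvis(ss=ss, pt=pt),
    )


def make_truth(
    subject_id="S0", age=30.0, sex="F", pi=49.0, ss=37.0, ll=40.0, tk=39.0,
    sva=0.3, cobb=5.0, apex="T8", rotation=3.0,
) -> TruthRecord:
    return TruthRecord(
        subject_id=subject_id, age=age, sex=sex, pi=pi, pt=pi - ss, ss=ss,
        ll=ll, tk=tk, sva=sva, cobb=cobb, apex=apex, rotation=rotation,
    )


@pytest.fixture(scope="session")
def cfg() -> GeneratorConfig:
    return default_config()


@pytest.fixture(scope="session")
def small_cohort():
    """60 measured synthetic subjects as a cohort DataFrame (seeded)."""
    from spinemetrics.cohort import build_cohort
    from spinemetrics.synthetic import generate_cohort

    recons, truths = generate_cohort(default_config(n_subjects=60, seed=42))
    return build_cohort(recons), truths
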