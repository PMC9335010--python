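"""Parametric synthetic 3D spine generator with known ground truth.

The generator is the package's stand-in for a large radiographic database:
it draws per-subject ground-truth alignment parameters from a calibrated
population model and then realizes each subject as a full 3D landmark
reconstruction in closed form, so that every geometric measurement can be
tested by parameter recovery.

Sampling model (all couplings configurable):

* age group drawn from the cohort's stratum weights, age uniform within it;
* PI from a truncated normal;
* SS = a·PI + b + ε (truncated), PT = PI − SS exactly;
* LL from a linear regression on PI and age (negative age slope);
* TK from LL and age (both positive slopes);
* SVA from age;
* with probability ``prevalence`` the subject is scoliotic: the maximal
  coronal Cobb angle is 10° + a log-normal excess (mild curves most common);
  otherwise a sub-10° baseline; the apex level is categorical and the
  maximal axial rotation is linear in the Cobb angle.

Geometric realization: a pelvis realizing SS/PT/PI; a sagittal centerline of
two tangent-continuous circular arcs (lordotic below, kyphotic above, joined
at the T12–L1 disc) with vertebrae placed at morphology-table arc-length
intervals and endplates orthogonal to the local tangent, arcs solved so the
L1–L5 and T4–T12 endplate angles equal the truth exactly; a coronal
lateral-deviation bump with per-vertebra endplate tilts solved so the
all-pairs Cobb search returns exactly the truth Cobb at the requested apex;
a per-vertebra axial-rotation profile peaking at the apex; and a global
sagittal translation achieving the truth SVA.  Optional Gaussian landmark
noise is added last.
"""

from __future__ import annotations

import copy
import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .landmarks import (
    LEVELS,
    Endplate,
    PelvisLandmarks,
    Point3,
    SpineReconstruction,
    VertebraLandmarks,
    level_index,
    write_landmarks,
)

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "ConstructionError",
    "default_config",
    "sample_truth",
    "build_spine",
    "generate_cohort",
    "truth_table",
]

_DEG = math.pi / 180.0

AGE_GROUPS: tuple[tuple[str, float, float], ...] = (
    ("10-18", 10.0, 19.0),
    ("19-44", 19.0, 45.0),
    ("45-64", 45.0, 65.0),
    ("65-79", 65.0, 80.0),
    ("80+", 80.0, 96.0),
)


class ConstructionError(ValueError):
    """A truth record is geometrically unrealizable."""


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_morphology() -> dict:
    heights = dict(
        zip(
            LEVELS,
            [1.6, 1.7, 1.7, 1.8, 1.8, 1.9, 1.9, 2.0, 2.0, 2.1, 2.2, 2.3,
             2.4, 2.5, 2.6, 2.6, 2.6],
        )
    )
    widths = {lvl: 2.8 + 2.2 * i / 16 for i, lvl in enumerate(LEVELS)}
    depths = {lvl: 2.0 + 1.5 * i / 16 for i, lvl in enumerate(LEVELS)}
    return {
        "body_height": heights,          # cm, cranial->caudal growth
        "body_width": widths,            # left-right extent, cm
        "body_depth": depths,            # anterior-posterior extent, cm
        "disc_thoracic": 0.5,            # disc heights, cm
        "disc_lumbar": 1.0,
        "lumbosacral_disc": 1.0,
        "sacral_depth": 5.0,             # S1 endplate AP extent, cm
        "hip_offset": 7.0,               # sacral-center to hip-axis distance, cm
        "femoral_head_span": 17.5,       # distance between femoral heads, cm
    }


def _default_population() -> dict:
    # Calibrated so the recomputed marginals of a large cohort approximate a
    # mixed clinical population: PI 49/SS 37/LL 40/TK 39 deg, SVA 0.3 cm,
    # median Cobb ~10 deg at 50.9% scoliosis prevalence, mean rotation ~7 deg.
    # Age reference 34.58 y is the mean age implied by the stratum weights.
    return {
        "pi": {"mean": 49.0, "sd": 11.0, "min": 3.0, "max": 89.0},
        "ss_on_pi": {"slope": 0.55, "intercept": 10.05, "sd": 5.5,
                     "min": 2.0, "max": 75.0},
        "ll": {"pi_slope": 0.55, "age_slope": -0.12, "intercept": 17.20,
               "sd": 8.0, "min": -15.0, "max": 74.0,
               "sex_effect": {"F": 0.6, "M": -0.9}},
        "tk": {"ll_slope": 0.4, "age_slope": 0.1, "intercept": 19.54,
               "sd": 7.0, "min": -17.0, "max": 79.0,
               "sex_effect": {"F": -0.6, "M": 0.9}},
        "sva": {"age_slope": 0.06, "intercept": -1.775, "sd": 2.5,
                "min": -9.7, "max": 27.6},
        "scoliosis": {
            "prevalence": 0.509,
            "threshold": 10.0,
            "lognormal_mu": 1.933,
            "lognormal_sigma": 1.2,
            "max_cobb": 106.0,
            "baseline_min": 1.0,
            "baseline_max": 10.0,
            "apex_weights": {"T5": 0.04, "T6": 0.06, "T7": 0.10, "T8": 0.16,
                             "T9": 0.16, "T10": 0.12, "T11": 0.10, "T12": 0.10,
                             "L1": 0.09, "L2": 0.07},
            "rotation_slope": 0.4,
            "rotation_intercept": 1.0,
            "rotation_sd": 2.0,
            "rotation_max": 47.0,
        },
    }


@dataclass
class GeneratorConfig:
    """Distributions and geometry defaults for the synthetic cohort."""

    n_subjects: int = 100
    seed: int = 0
    landmark_noise_sd: float = 0.0   # cm, Gaussian per coordinate
    sex_ratio_female: float = 0.6
    age_group_weights: dict = field(
        default_factory=lambda: {  # cohort stratum fractions
            "10-18": 0.521, "19-44": 0.127, "45-64": 0.167,
            "65-79": 0.161, "80+": 0.024,
        }
    )
    population: dict = field(default_factory=_default_population)
    morphology: dict = field(default_factory=_default_morphology)
    #: L5 inferior endplate tilt: "balance" solves it so the spine meets the
    #: target SVA with (near-)zero translation, giving an anatomically
    #: coherent curve; a float is interpreted as a fixed fraction of SS.
    phi_base: str | float = "balance"
    #: half-width of the coronal deformity span in levels (span = 2k+1).
    curve_half_span: int = 3
    #: lateral apex deviation per degree of Cobb angle, cm/deg.
    lateral_amplitude_per_deg: float = 0.05

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be non-negative")
        if self.landmark_noise_sd < 0:
            raise ConfigError("landmark_noise_sd must be >= 0")
        w = self.age_group_weights
        if abs(sum(w.values()) - 1.0) > 1e-6 or any(v < 0 for v in w.values()):
            raise ConfigError("age_group_weights must be non-negative and sum to 1")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ConfigError("sex_ratio_female must lie in [0, 1]")
        sc = self.population["scoliosis"]
        if not 0.0 <= sc["prevalence"] <= 1.0:
            raise ConfigError("scoliosis prevalence must lie in [0, 1]")
        if abs(sum(sc["apex_weights"].values()) - 1.0) > 1e-6:
            raise ConfigError("apex_weights must sum to 1")
        for name in ("pi", "ss_on_pi", "ll", "tk", "sva"):
            d = self.population[name]
            if d["min"] >= d["max"]:
                raise ConfigError(f"{name}: min must be < max")
            if d["sd"] < 0:
                raise ConfigError(f"{name}: sd must be >= 0")

    def to_dict(self) -> dict:
        return copy.deepcopy(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        base = cls()
        merged = base.to_dict()

        def _merge(dst, src):
            for k, v in src.items():
                if isinstance(v, dict) and isinstance(dst.get(k), dict):
                    _merge(dst[k], v)
                else:
                    dst[k] = v

        _merge(merged, d)
        cfg = cls(**merged)
        cfg.validate()
        return cfg


def default_config(**overrides) -> GeneratorConfig:
    """The shipped population-calibrated configuration."""
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Truth sampling
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground-truth parameters of one synthetic subject."""

    subject_id: str
    age: float
    sex: str
    pi: float
    pt: float
    ss: float
    ll: float      # L1-L5 lordosis, degrees
    tk: float      # T4-T12 kyphosis, degrees
    sva: float     # cm
    cobb: float    # maximal coronal Cobb angle, degrees
    apex: str      # apex level of the coronal curve
    rotation: float  # maximal axial rotation, degrees

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _trunc_normal(rng: np.random.Generator, mu: float, sd: float,
                  lo: float, hi: float, what: str) -> float:
    if sd == 0:
        return min(max(mu, lo), hi)
    if hi < mu - 6 * sd or lo > mu + 6 * sd:
        raise ConfigError(
            f"{what}: truncation bounds [{lo}, {hi}] exclude mean {mu} +/- 6 sd"
        )
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return x
    return min(max(mu, lo), hi)


def sample_truth(cfg: GeneratorConfig, rng: np.random.Generator,
                 subject_id: str = "S0") -> TruthRecord:
    """Draw one ground-truth record from the population model."""
    pop = cfg.population
    groups = list(cfg.age_group_weights)
    weights = np.array([cfg.age_group_weights[g] for g in groups], dtype=float)
    group = groups[rng.choice(len(groups), p=weights / weights.sum())]
    lo, hi = next((a, b) for g, a, b in AGE_GROUPS if g == group)
    age = float(rng.uniform(lo, hi))
    sex = "F" if rng.uniform() < cfg.sex_ratio_female else "M"

    d = pop["pi"]
    pi = _trunc_normal(rng, d["mean"], d["sd"], d["min"], d["max"], "pi")
    d = pop["ss_on_pi"]
    ss = _trunc_normal(rng, d["slope"] * pi + d["intercept"], d["sd"],
                       d["min"], d["max"], "ss")
    pt = pi - ss
    d = pop["ll"]
    mu = (d["intercept"] + d["pi_slope"] * pi + d["age_slope"] * age
          + d["sex_effect"][sex])
    ll = _trunc_normal(rng, mu, d["sd"], d["min"], d["max"], "ll")
    d = pop["tk"]
    mu = (d["intercept"] + d["ll_slope"] * ll + d["age_slope"] * age
          + d["sex_effect"][sex])
    tk = _trunc_normal(rng, mu, d["sd"], d["min"], d["max"], "tk")
    d = pop["sva"]
    sva = _trunc_normal(rng, d["intercept"] + d["age_slope"] * age, d["sd"],
                        d["min"], d["max"], "sva")

    sc = pop["scoliosis"]
    if rng.uniform() < sc["prevalence"]:
        excess = float("inf")
        while sc["threshold"] + excess > sc["max_cobb"]:
            excess = rng.lognormal(sc["lognormal_mu"], sc["lognormal_sigma"])
        cobb = sc["threshold"] + excess
    else:
        cobb = float(rng.uniform(sc["baseline_min"], sc["baseline_max"]))
    apex_levels = list(sc["apex_weights"])
    aw = np.array([sc["apex_weights"][k] for k in apex_levels], dtype=float)
    apex = apex_levels[rng.choice(len(apex_levels), p=aw / aw.sum())]
    rotation = sc["rotation_intercept"] + sc["rotation_slope"] * cobb
    if sc["rotation_sd"] > 0:
        rotation += rng.normal(0.0, sc["rotation_sd"])
    rotation = min(max(rotation, 0.0), sc["rotation_max"])

    return TruthRecord(
        subject_id=subject_id, age=age, sex=sex,
        pi=pi, pt=pt, ss=ss, ll=ll, tk=tk, sva=sva,
        cobb=cobb, apex=apex, rotation=rotation,
    )


# ---------------------------------------------------------------------------
# Geometric realization
# ---------------------------------------------------------------------------

def _arc_positions(cfg: GeneratorConfig) -> dict:
    """Arc-length stations (cm) of every endplate/center, from L5-inferior up."""
    m = cfg.morphology
    s_inf, s_sup, s_center = {}, {}, {}
    s = 0.0
    for lvl in reversed(LEVELS):  # L5 -> T1
        h = m["body_height"][lvl]
        s_inf[lvl] = s
        s_center[lvl] = s + h / 2
        s_sup[lvl] = s + h
        s = s + h + (m["disc_lumbar"] if lvl.startswith("L") else m["disc_thoracic"])
    return {"inf": s_inf, "sup": s_sup, "center": s_center}


def _arc_point(s: float, phi0: float, kappa: float) -> tuple[float, float, float]:
    """(y, z, phi) at arc length s along a circular arc from the origin.

    ``phi`` is the tangent tilt versus vertical (anterior positive, radians);
    dy/ds = sin(phi), dz/ds = cos(phi).
    """
    phi = phi0 + kappa * s
    if abs(kappa) < 1e-12:
        return s * math.sin(phi0), s * math.cos(phi0), phi
    y = (math.cos(phi0) - math.cos(phi)) / kappa
    z = (math.sin(phi) - math.sin(phi0)) / kappa
    return y, z, phi


def _endplate_at(center: np.ndarray, delta_rad: float, coronal_rad: float,
                 axial_rad: float, width: float, depth: float) -> Endplate:
    """Closed-form endplate whose measured tilts equal the targets exactly.

    The left–right axis L is solved so its transverse projection makes the
    axial-rotation angle with x and its coronal projection makes the coronal
    tilt; the anterior axis A is solved orthogonal to L with the prescribed
    sagittal tilt.
    """
    if max(abs(coronal_rad), abs(axial_rad)) > 89.0 * _DEG:
        raise ConstructionError("endplate tilt beyond 89 deg is not realizable")
    L = np.array([1.0, math.tan(axial_rad), math.tan(coronal_rad)])
    L /= np.linalg.norm(L)
    cos_d, sin_d = math.cos(delta_rad), math.sin(delta_rad)
    ax = -(cos_d * L[1] - sin_d * L[2]) / L[0]
    A = np.array([ax, cos_d, -sin_d])
    A /= np.linalg.norm(A)
    w2, d2 = width / 2, depth / 2
    return Endplate(
        anterior=Point3(*(center + d2 * A)),
        posterior=Point3(*(center - d2 * A)),
        left=Point3(*(center + w2 * L)),
        right=Point3(*(center - w2 * L)),
        center=Point3(*center),
    )


def _deformity_profiles(cfg: GeneratorConfig, t: TruthRecord) -> tuple:
    """Per-level coronal tilt, axial rotation (deg) and lateral offset (cm)."""
    n = len(LEVELS)
    tilt = np.zeros(n)
    rot = np.zeros(n)
    lat = np.zeros(n)
    a = level_index(t.apex)
    k = cfg.curve_half_span
    start, end = max(0, a - k), min(n - 1, a + k)
    a = min(max(a, start + 1), end - 1)  # apex strictly inside the span
    half = t.cobb / 2.0
    if half >= 89.0:
        raise ConstructionError(f"Cobb angle {t.cobb:.1f} deg is not realizable")
    amp = cfg.lateral_amplitude_per_deg * t.cobb
    for i in range(start, end + 1):
        if i <= a:
            u = (i - start) / (a - start)
            tilt[i] = -half * math.cos(math.pi / 2 * u)
            bump = math.sin(math.pi / 2 * u)
        else:
            u = (i - a) / (end - a)
            tilt[i] = half * math.sin(math.pi / 2 * u)
            bump = math.cos(math.pi / 2 * u)
        rot[i] = t.rotation * bump
        lat[i] = amp * bump
    return tilt, rot, lat


def _solve_phi_base(t: TruthRecord, cfg: GeneratorConfig, st: dict,
                    arc_yz, base: np.ndarray, pelvis: PelvisLandmarks,
                    ss_r: float) -> float:
    """Tangent tilt at the L5 inferior endplate.

    With the default "balance" policy the tilt is solved (bisection on a
    closed-form expression) so the T1 body center lands at the truth SVA
    without a global translation; the residual translation then only absorbs
    numerical round-off.  Searching is restricted so the tangent never
    exceeds 85 deg anywhere along the curve (which would fold the spine).
    """
    if not isinstance(cfg.phi_base, str):
        return float(cfg.phi_base) * ss_r

    s_t1 = 0.5 * (st["sup"]["T1"] + st["inf"]["T1"])

    def offset(phi0: float) -> float:
        y_sup = arc_yz(st["sup"]["T1"], phi0)[0]
        y_inf = arc_yz(st["inf"]["T1"], phi0)[0]
        y_t1 = base[1] + 0.5 * (y_sup + y_inf)
        return y_t1 - pelvis.sacral_posterior.y - t.sva

    # tangent sweep relative to phi0 at every endplate station
    rel = [arc_yz(s, 0.0)[2] for s in
           [st[k][lvl] for k in ("sup", "inf") for lvl in LEVELS]]
    limit = 85.0 * _DEG
    lo, hi = -limit - min(rel), limit - max(rel)
    if lo >= hi:
        raise ConstructionError(
            f"sagittal curvature (LL={t.ll:.1f}, TK={t.tk:.1f}) folds the spine"
        )
    f_lo, f_hi = offset(lo), offset(hi)
    if f_lo * f_hi > 0:
        # no balanced solution inside the admissible tilt range: take the
        # endpoint closest to balance; the global translation absorbs the rest
        return lo if abs(f_lo) < abs(f_hi) else hi
    from scipy.optimize import brentq

    return float(brentq(offset, lo, hi, xtol=1e-12))


def build_spine(t: TruthRecord, cfg: GeneratorConfig | None = None,
                rng: np.random.Generator | None = None) -> SpineReconstruction:
    """Realize a truth record as a 3D landmark reconstruction.

    Noiseless output reproduces every truth parameter exactly (PI/PT/SS, LL,
    TK, SVA, Cobb + apex, maximal rotation) when measured by the geometry
    module.
    """
    cfg = cfg or default_config()
    m = cfg.morphology
    if abs(t.ll) > 120 or abs(t.tk) > 120:
        raise ConstructionError("regional angle beyond 120 deg is not realizable")
    if t.rotation >= 90:
        raise ConstructionError("axial rotation beyond 90 deg is not realizable")

    # --- pelvis realizing SS, PT (hence PI) --------------------------------
    ss_r, pt_r = t.ss * _DEG, t.pt * _DEG
    sc = np.zeros(3)
    plate_dir = np.array([0.0, math.cos(ss_r), -math.sin(ss_r)])  # post -> ant
    d2 = m["sacral_depth"] / 2
    hip_mid = sc + m["hip_offset"] * np.array(
        [0.0, math.sin(pt_r), -math.cos(pt_r)]
    )
    span2 = m["femoral_head_span"] / 2
    pelvis = PelvisLandmarks(
        femoral_head_left=Point3(*(hip_mid + np.array([span2, 0.0, 0.0]))),
        femoral_head_right=Point3(*(hip_mid - np.array([span2, 0.0, 0.0]))),
        sacral_anterior=Point3(*(sc + d2 * plate_dir)),
        sacral_posterior=Point3(*(sc - d2 * plate_dir)),
        sacral_center=Point3(*sc),
    )

    # --- two-arc sagittal centerline ---------------------------------------
    st = _arc_positions(cfg)
    lumbar_len = st["sup"]["L1"]       # L5-inf (s=0) to L1-sup
    kappa_l = -(t.ll * _DEG) / lumbar_len
    s_junction = 0.5 * (st["sup"]["L1"] + st["inf"]["T12"])
    tk_len = st["sup"]["T4"] - st["inf"]["T12"]
    kappa_k = (t.tk * _DEG) / tk_len

    up_normal = np.array([0.0, math.sin(ss_r), math.cos(ss_r)])
    base = sc + m["lumbosacral_disc"] * up_normal  # L5 inferior endplate center

    def _arc_yz(s: float, phi0: float) -> tuple[float, float, float]:
        if s <= s_junction:
            return _arc_point(s, phi0, kappa_l)
        yj, zj, phij = _arc_point(s_junction, phi0, kappa_l)
        y, z, phi = _arc_point(s - s_junction, phij, kappa_k)
        return yj + y, zj + z, phi

    phi0 = _solve_phi_base(t, cfg, st, _arc_yz, base, pelvis, ss_r)

    def centerline(s: float) -> tuple[np.ndarray, float]:
        y, z, phi = _arc_yz(s, phi0)
        return base + np.array([0.0, y, z]), phi

    tilt_deg, rot_deg, lat = _deformity_profiles(cfg, t)

    vertebrae = []
    for i, lvl in enumerate(LEVELS):
        w, d = m["body_width"][lvl], m["body_depth"][lvl]
        offset = np.array([lat[i], 0.0, 0.0])
        plates = {}
        for side, key in (("superior", "sup"), ("inferior", "inf")):
            p, phi = centerline(st[key][lvl])
            plates[side] = _endplate_at(
                p + offset, phi, tilt_deg[i] * _DEG, rot_deg[i] * _DEG, w, d
            )
        vertebrae.append(VertebraLandmarks(level=lvl, superior=plates["superior"],
                                           inferior=plates["inferior"]))

    # --- global sagittal translation achieving SVA -------------------------
    t1_center = vertebrae[0].body_center()
    dy = t.sva - (t1_center[1] - pelvis.sacral_posterior.y)
    shift = np.array([0.0, dy, 0.0])

    def _shift_plate(e: Endplate, delta: np.ndarray) -> Endplate:
        return Endplate(**{k: Point3(*(getattr(e, k).as_array() + delta))
                           for k in ("anterior", "posterior", "left", "right",
                                     "center")})

    vertebrae = [
        VertebraLandmarks(level=v.level,
                          superior=_shift_plate(v.superior, shift),
                          inferior=_shift_plate(v.inferior, shift))
        for v in vertebrae
    ]

    recon = SpineReconstruction(
        subject_id=t.subject_id, age=t.age, sex=t.sex,
        vertebrae=vertebrae, pelvis=pelvis,
    )

    if cfg.landmark_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        recon = _add_noise(recon, cfg.landmark_noise_sd, rng)
    return recon


def _add_noise(r: SpineReconstruction, sd: float,
               rng: np.random.Generator) -> SpineReconstruction:
    def _noisy_point(p: Point3) -> Point3:
        return Point3(*(p.as_array() + rng.normal(0.0, sd, 3)))

    def _noisy_plate(e: Endplate) -> Endplate:
        return Endplate(**{k: _noisy_point(getattr(e, k))
                           for k in ("anterior", "posterior", "left", "right",
                                     "center")})

    vertebrae = [
        VertebraLandmarks(level=v.level, superior=_noisy_plate(v.superior),
                          inferior=_noisy_plate(v.inferior))
        for v in r.vertebrae
    ]
    p = r.pelvis
    pelvis = PelvisLandmarks(
        femoral_head_left=_noisy_point(p.femoral_head_left),
        femoral_head_right=_noisy_point(p.femoral_head_right),
        sacral_anterior=_noisy_point(p.sacral_anterior),
        sacral_posterior=_noisy_point(p.sacral_posterior),
        sacral_center=_noisy_point(p.sacral_center),
    )
    return SpineReconstruction(subject_id=r.subject_id, age=r.age, sex=r.sex,
                               vertebrae=vertebrae, pelvis=pelvis)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    cfg: GeneratorConfig,
    out_dir: str | Path | None = None,
    landmark_format: str = "json",
) -> tuple[list[SpineReconstruction], list[TruthRecord]]:
    """Generate ``cfg.n_subjects`` paired reconstructions and truth records.

    Fully reproducible from ``cfg.seed``.  If ``out_dir`` is given, writes
    ``landmarks.json`` (or ``.csv``), ``truth.csv`` and the resolved config.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    recons, truths = [], []
    for i in range(cfg.n_subjects):
        t = sample_truth(cfg, rng, subject_id=f"S{i:05d}")
        try:
            recons.append(build_spine(t, cfg, rng))
        except ConstructionError as exc:
            raise ConstructionError(f"subject {i} ({t.subject_id}): {exc}") from exc
        truths.append(t)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_landmarks(recons, out_dir / f"landmarks.{landmark_format}",
                        format=landmark_format)
        write_truth(truths, out_dir / "truth.csv")
        (out_dir / "generator_config.json").write_text(
            json.dumps(cfg.to_dict(), sort_keys=True, indent=1)
        )
    return recons, truths


_TRUTH_COLUMNS = ("subject_id", "age", "sex", "pi", "pt", "ss", "ll", "tk",
                  "sva", "cobb", "apex", "rotation")


def write_truth(truths: Sequence[TruthRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TRUTH_COLUMNS)
        for t in truths:
            w.writerow([getattr(t, c) for c in _TRUTH_COLUMNS])
    return path


def truth_table(truths: Sequence[TruthRecord]):
    """Truth records as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame([t.as_dict() for t in truths])
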