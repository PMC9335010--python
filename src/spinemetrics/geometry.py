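"""Radiological spinal-alignment parameters from 3D landmarks.

All angles are computed in radians internally and reported in degrees.

Sign conventions (chosen so that the exact sagittal identity PI = PT + SS
holds and typical standing anatomy yields the conventional positive values):

* Sagittal endplate tilt ``delta`` — angle of the posterior→anterior endplate
  line versus the horizontal, positive when the *posterior* margin is cranial
  to the anterior margin (the anatomical configuration of the S1 endplate:
  it slopes caudally toward the promontory).
* Sacral slope SS = ``delta`` of the S1 superior endplate.
* Pelvic tilt PT — angle between the vertical and the hip-axis→sacral-center
  line, positive when the sacral center is posterior to the hip axis.
* Pelvic incidence PI — angle between the caudal perpendicular to the sacral
  endplate at its midpoint and the sacral-center→hip-axis line; geometrically
  identical to PT + SS.
* Lumbar lordosis (lordosis positive) = delta(lower inferior endplate) −
  delta(upper superior endplate); thoracic kyphosis is the opposite sign.
* SVA — anterior (+y) offset of the cranial reference body center (default
  T1, the most cranial reconstructed vertebra) from the posterior margin of
  the sacral endplate, in cm.
* Coronal endplate tilt — angle of the right→left endplate line versus the
  horizontal in the coronal (x, z) projection.
* Axial rotation — unsigned angle between the transverse projection of a
  vertebra's left–right axis and the global x-axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.interpolate import CubicSpline

from .landmarks import (
    LEVELS,
    Endplate,
    PelvisLandmarks,
    SpineReconstruction,
    level_index,
)

__all__ = [
    "Line2D",
    "SpineParameters",
    "endplate_line",
    "sagittal_tilt",
    "coronal_tilt",
    "sacral_slope",
    "pelvic_tilt",
    "pelvic_incidence",
    "regional_angle",
    "coronal_cobb_max",
    "sva",
    "t1_pelvic_angle",
    "axial_rotation_max",
    "roussouly_lordosis",
    "compute_all",
]

_DEG = 180.0 / math.pi


class DegenerateGeometryError(ValueError):
    """Two landmarks that must span a line coincide in the projection."""


@dataclass(frozen=True)
class Line2D:
    """An oriented line in a 2D projection plane."""

    point: np.ndarray      # (2,) a point on the line
    direction: np.ndarray  # (2,) unit direction

    @property
    def angle_deg(self) -> float:
        """Signed angle of the direction versus the first (horizontal) axis."""
        return math.atan2(self.direction[1], self.direction[0]) * _DEG


def _project(p: np.ndarray, plane: str) -> np.ndarray:
    if plane == "sagittal":
        return p[[1, 2]]  # (y, z)
    if plane == "coronal":
        return p[[0, 2]]  # (x, z)
    if plane == "transverse":
        return p[[0, 1]]  # (x, y)
    raise ValueError(f"unknown plane {plane!r}")


def endplate_line(e: Endplate, plane: str) -> Line2D:
    """Oriented 2D endplate line in a projection plane.

    Sagittal: through the projected anterior and posterior landmarks,
    oriented posterior→anterior.  Coronal: through the projected left and
    right landmarks, oriented right→left.
    """
    if plane == "sagittal":
        a = _project(e.posterior.as_array(), plane)
        b = _project(e.anterior.as_array(), plane)
    elif plane == "coronal":
        a = _project(e.right.as_array(), plane)
        b = _project(e.left.as_array(), plane)
    else:
        raise ValueError(f"endplate lines are defined in sagittal/coronal, not {plane!r}")
    d = b - a
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise DegenerateGeometryError(f"degenerate endplate in {plane} projection")
    return Line2D(point=a, direction=d / n)


def sagittal_tilt(e: Endplate) -> float:
    """Sagittal endplate tilt in degrees, posterior-up positive."""
    a, p = e.anterior.as_array(), e.posterior.as_array()
    dy, dz = a[1] - p[1], a[2] - p[2]
    if abs(dy) < 1e-12 and abs(dz) < 1e-12:
        raise DegenerateGeometryError("coincident anterior/posterior landmarks")
    return math.atan2(-dz, dy) * _DEG


def coronal_tilt(e: Endplate) -> float:
    """Coronal endplate tilt in degrees (right→left line vs horizontal)."""
    return endplate_line(e, "coronal").angle_deg


# ---------------------------------------------------------------------------
# Spinopelvic parameters
# ---------------------------------------------------------------------------

def sacral_slope(p: PelvisLandmarks) -> float:
    """Sacral slope in degrees: tilt of the S1 superior endplate line."""
    a = _project(p.sacral_anterior.as_array(), "sagittal")
    b = _project(p.sacral_posterior.as_array(), "sagittal")
    d = a - b  # posterior -> anterior, (y, z)
    if np.linalg.norm(d) < 1e-9:
        raise DegenerateGeometryError("degenerate sacral endplate line")
    return math.atan2(-d[1], d[0]) * _DEG


def pelvic_tilt(p: PelvisLandmarks) -> float:
    """Pelvic tilt in degrees, positive with the sacral center posterior."""
    v = p.sacral_center.as_array() - p.hip_axis()
    vy, vz = v[1], v[2]
    if math.hypot(vy, vz) < 1e-9:
        raise DegenerateGeometryError("hip axis coincident with sacral center")
    return math.atan2(-vy, vz) * _DEG


def pelvic_incidence(p: PelvisLandmarks) -> float:
    """Pelvic incidence in degrees, computed geometrically.

    The angle is taken between the caudal perpendicular to the sacral
    endplate at ``sacral_center`` and the sacral-center→hip-axis line in the
    sagittal plane; by construction it equals PT + SS to machine precision.
    """
    a = _project(p.sacral_anterior.as_array(), "sagittal")
    b = _project(p.sacral_posterior.as_array(), "sagittal")
    e = a - b
    ne = np.linalg.norm(e)
    if ne < 1e-9:
        raise DegenerateGeometryError("degenerate sacral endplate line")
    e = e / ne
    n = np.array([e[1], -e[0]])  # caudal (posterior-down) perpendicular
    u = _project(p.hip_axis() - p.sacral_center.as_array(), "sagittal")
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise DegenerateGeometryError("hip axis coincident with sacral center")
    u = u / nu
    return math.atan2(n[0] * u[1] - n[1] * u[0], float(n @ u)) * _DEG


# ---------------------------------------------------------------------------
# Regional sagittal angles
# ---------------------------------------------------------------------------

def regional_angle(
    s: SpineReconstruction,
    upper: str,
    lower: str,
    plane: str = "sagittal",
    sign_convention: str = "lordosis",
) -> float:
    """Signed angle between upper's superior and lower's inferior endplates.

    ``sign_convention`` "lordosis" yields positive values for posteriorly
    concave (lordotic) curves, "kyphosis" for anteriorly concave ones.
    """
    if level_index(upper) >= level_index(lower):
        raise ValueError(f"{upper} is not cranial to {lower}")
    if plane != "sagittal":
        raise ValueError("regional angles are sagittal measurements")
    d_up = sagittal_tilt(s.vertebra(upper).superior)
    d_lo = sagittal_tilt(s.vertebra(lower).inferior)
    angle = d_lo - d_up
    if sign_convention == "kyphosis":
        angle = -angle
    elif sign_convention != "lordosis":
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    return angle


# ---------------------------------------------------------------------------
# Coronal Cobb angle
# ---------------------------------------------------------------------------

def _line_angle_between(a_deg: float, b_deg: float) -> float:
    """Unsigned angle in [0, 180] between two consistently oriented lines.

    The endplate lines are oriented right→left, so severe curves beyond 90°
    (Cobb angles up to ~106° occur in real populations) are represented
    correctly rather than folding back below 90°.
    """
    d = abs(a_deg - b_deg) % 360.0
    return min(d, 360.0 - d)


def coronal_cobb_max(s: SpineReconstruction) -> dict:
    """Maximal coronal Cobb angle over all T1..L5 level pairs.

    Returns ``{"angle", "upper_end", "lower_end", "apex"}``.  The end pair
    maximizes the unsigned coronal angle between the upper vertebra's
    superior and the lower vertebra's inferior endplate lines (ties broken
    toward the most cranial, then shortest, curve); the apex is the vertebra
    between the ends whose body center lies farthest, in the coronal
    projection, from the line joining the end vertebrae's centers.
    """
    sup = [coronal_tilt(v.superior) for v in s.vertebrae]
    inf = [coronal_tilt(v.inferior) for v in s.vertebrae]
    best, best_pair = -1.0, (0, 1)
    for u, lo in combinations(range(len(LEVELS)), 2):
        ang = _line_angle_between(sup[u], inf[lo])
        if ang > best + 1e-12:
            best, best_pair = ang, (u, lo)
    u, lo = best_pair
    centers = np.stack([v.body_center() for v in s.vertebrae])
    cu, cl = _project(centers[u], "coronal"), _project(centers[lo], "coronal")
    axis = cl - cu
    n = np.linalg.norm(axis)
    if n < 1e-9:  # cannot happen for a valid spine (z strictly decreasing)
        axis = np.array([0.0, -1.0])
    else:
        axis = axis / n
    dists = []
    for k in range(u, lo + 1):
        d = _project(centers[k], "coronal") - cu
        dists.append(abs(axis[0] * d[1] - axis[1] * d[0]))
    apex = u + int(np.argmax(dists))
    return {
        "angle": max(best, 0.0),
        "upper_end": LEVELS[u],
        "lower_end": LEVELS[lo],
        "apex": LEVELS[apex],
    }


# ---------------------------------------------------------------------------
# Global sagittal balance
# ---------------------------------------------------------------------------

def sva(s: SpineReconstruction, reference: str = "T1") -> float:
    """Sagittal vertical axis in cm, anterior positive.

    The y offset of the cranial reference body center (default T1, the most
    cranial reconstructed vertebra) from the posterior margin of the S1
    endplate.
    """
    ref = s.vertebra(reference).body_center()
    return float(ref[1] - s.pelvis.sacral_posterior.y)


def t1_pelvic_angle(s: SpineReconstruction) -> float:
    """T1-pelvic angle in degrees.

    Sagittal angle at the hip axis between the line to the T1 body center
    and the line to the sacral endplate midpoint; equals PT plus the signed
    (anterior-positive) inclination of the hip-axis→T1 line versus vertical.
    """
    hip = s.pelvis.hip_axis()
    a = _project(s.vertebra("T1").body_center() - hip, "sagittal")
    b = _project(s.pelvis.sacral_center.as_array() - hip, "sagittal")
    if np.linalg.norm(a) < 1e-9 or np.linalg.norm(b) < 1e-9:
        raise DegenerateGeometryError("hip axis coincident with a TPA reference point")
    theta_t1 = math.atan2(a[0], a[1])   # anterior-positive tilt vs vertical
    theta_sc = math.atan2(-b[0], b[1])  # posterior-positive tilt (= PT)
    return (theta_t1 + theta_sc) * _DEG


# ---------------------------------------------------------------------------
# Axial rotation
# ---------------------------------------------------------------------------

def axial_rotation_max(s: SpineReconstruction, tilt_cutoff_deg: float = 85.0) -> dict:
    """Maximal transverse-plane vertebral rotation, ``{"angle", "level"}``.

    Each vertebra's left–right axis is the mean of the (left − right)
    vectors of its two endplates; the rotation is the unsigned angle between
    its transverse projection and the global x-axis.  Vertebrae whose axis
    is tilted more than ``tilt_cutoff_deg`` out of the transverse plane are
    excluded from the maximum with a warning.
    """
    best, best_level = -1.0, LEVELS[0]
    min_frac = math.cos(math.radians(tilt_cutoff_deg))
    for v in s.vertebrae:
        axis = 0.5 * (
            (v.superior.left.as_array() - v.superior.right.as_array())
            + (v.inferior.left.as_array() - v.inferior.right.as_array())
        )
        norm = np.linalg.norm(axis)
        proj = _project(axis, "transverse")
        pn = np.linalg.norm(proj)
        if norm < 1e-9 or pn / norm < min_frac:
            warnings.warn(
                f"{v.level}: left-right axis nearly orthogonal to the transverse "
                "plane; excluded from the rotation maximum",
                stacklevel=2,
            )
            continue
        if proj[0] < 0:
            proj = -proj
        rot = abs(math.atan2(proj[1], proj[0])) * _DEG
        if rot > best + 1e-12:
            best, best_level = rot, v.level
    return {"angle": max(best, 0.0), "level": best_level}


# ---------------------------------------------------------------------------
# Roussouly lordosis
# ---------------------------------------------------------------------------

def roussouly_lordosis(s: SpineReconstruction, n_grid: int = 600) -> dict:
    """Lordosis up to the sagittal inflection point, ``{"angle", "inflection"}``.

    A natural cubic spline is fit through the sagittal projections of the
    sacral endplate midpoint and the 17 body centers (caudal→cranial,
    parametrized by cumulative chord length).  The inflection is the most
    caudal point, walking cranially from S1, where the signed curvature
    switches from lordotic (tangent rotating posteriorly) to kyphotic; the
    reported level is the vertebra nearest that point.  The angle is taken
    between the sacral endplate line and the endplate-parallel direction
    (perpendicular to the spline tangent) at the inflection — i.e. the
    tangent sweep of the lordotic arc.  If the curvature never changes sign
    the inflection is T1 and the angle spans the whole curve.
    """
    pts = [_project(s.pelvis.sacral_center.as_array(), "sagittal")]
    pts += [_project(v.body_center(), "sagittal") for v in s.vertebrae[::-1]]
    pts = np.stack(pts)  # caudal -> cranial, (y, z)
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    spline = CubicSpline(t, pts, axis=0, bc_type="natural")

    # tangent tilt vs vertical at each body center (t[1]=L5 ... t[-1]=T1);
    # the curvature sign is read from tangent differences at vertebra
    # resolution, which is robust to spline flutter between data points
    d1 = spline(t[1:], 1)
    phi_c = np.arctan2(d1[:, 0], d1[:, 1])
    dphi = np.diff(phi_c)  # < 0: lordotic (tangent rotating posteriorly)
    eps = math.radians(0.2)

    levels_cc = LEVELS[::-1]  # caudal -> cranial
    t_inflection, level = None, "T1"
    seen_lordotic = False
    for i, val in enumerate(dphi):
        if val < -eps:
            seen_lordotic = True
        elif seen_lordotic and val > eps:
            nxt = dphi[i + 1] if i + 1 < len(dphi) else eps
            if nxt > -eps:  # persistent sign change, not flutter
                t_inflection = 0.5 * (t[1 + i] + t[2 + i])
                level = levels_cc[i + 1]
                break
    if t_inflection is None:
        t_inflection = t[-1]

    tan = spline(t_inflection, 1)
    phi = math.atan2(tan[0], tan[1]) * _DEG  # tangent tilt vs vertical, anterior+
    angle = sacral_slope(s.pelvis) - phi
    return {"angle": angle, "inflection": level}


# ---------------------------------------------------------------------------
# Full parameter panel
# ---------------------------------------------------------------------------

@dataclass
class SpineParameters:
    """The full computed radiological parameter panel for one subject."""

    pi: float
    pt: float
    ss: float
    ll_l1l5: float
    ll_roussouly: float
    roussouly_inflection: str
    tk_t1t12: float
    tk_t4t12: float
    pi_ll: float
    sva: float
    tpa: float
    cobb_angle: float
    cobb_upper: str
    cobb_lower: str
    cobb_apex: str
    rot_angle: float
    rot_level: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_all(s: SpineReconstruction, sva_reference: str = "T1") -> SpineParameters:
    """Compute every radiological parameter from one reconstruction."""
    pt = pelvic_tilt(s.pelvis)
    ss = sacral_slope(s.pelvis)
    pi = pelvic_incidence(s.pelvis)
    ll = regional_angle(s, "L1", "L5", sign_convention="lordosis")
    rous = roussouly_lordosis(s)
    cobb = coronal_cobb_max(s)
    rot = axial_rotation_max(s)
    return SpineParameters(
        pi=pi,
        pt=pt,
        ss=ss,
        ll_l1l5=ll,
        ll_roussouly=rous["angle"],
        roussouly_inflection=rous["inflection"],
        tk_t1t12=regional_angle(s, "T1", "T12", sign_convention="kyphosis"),
        tk_t4t12=regional_angle(s, "T4", "T12", sign_convention="kyphosis"),
        pi_ll=pi - ll,
        sva=sva(s, reference=sva_reference),
        tpa=t1_pelvic_angle(s),
        cobb_angle=cobb["angle"],
        cobb_upper=cobb["upper_end"],
        cobb_lower=cobb["lower_end"],
        cobb_apex=cobb["apex"],
        rot_angle=rot["angle"],
        rot_level=rot["level"],
    )
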