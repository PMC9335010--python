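"""3D vertebral/pelvic landmark data model and file IO.

Coordinate frame (right-handed, units cm):

* ``x`` — left (+) / right (−)
* ``y`` — anterior (+) / posterior (−)
* ``z`` — cranial (+) / caudal (−)

so the sagittal plane is (y, z), the coronal plane (x, z) and the transverse
plane (x, y).  The origin is arbitrary per subject: every parameter computed
downstream is translation invariant (the sagittal vertical axis is an internal
difference between two of the subject's own landmarks).

Each vertebra T1..L5 carries 10 landmarks: two endplates with five points each
(anterior, posterior, left and right margins plus the center).  The pelvis
carries the two femoral-head centers and the anterior/posterior margins and
midpoint of the S1 superior endplate.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LEVELS",
    "Point3",
    "Endplate",
    "VertebraLandmarks",
    "PelvisLandmarks",
    "SpineReconstruction",
    "SchemaError",
    "read_landmarks",
    "write_landmarks",
    "validate_reconstruction",
]

#: Canonical cranial-to-caudal order of the modelled levels.
LEVELS: tuple[str, ...] = tuple(f"T{i}" for i in range(1, 13)) + tuple(
    f"L{i}" for i in range(1, 6)
)

_LEVEL_INDEX = {lvl: i for i, lvl in enumerate(LEVELS)}

_ENDPLATE_KEYS = ("anterior", "posterior", "left", "right", "center")
_PELVIS_KEYS = (
    "femoral_head_left",
    "femoral_head_right",
    "sacral_anterior",
    "sacral_posterior",
    "sacral_center",
)


class SchemaError(ValueError):
    """Raised when a landmark file violates the documented schema."""


def level_index(level: str) -> int:
    """Position of a level in the canonical T1→L5 order."""
    try:
        return _LEVEL_INDEX[level]
    except KeyError:
        raise SchemaError(f"unknown vertebral level {level!r}") from None


@dataclass(frozen=True)
class Point3:
    """A 3D landmark position in cm."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise SchemaError(f"non-finite coordinate in {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "Point3":
        if len(a) != 3:
            raise SchemaError(f"expected 3 coordinates, got {len(a)}")
        return Point3(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class Endplate:
    """Five landmarks of one vertebral endplate."""

    anterior: Point3
    posterior: Point3
    left: Point3
    right: Point3
    center: Point3

    def points(self) -> tuple[Point3, ...]:
        return (self.anterior, self.posterior, self.left, self.right, self.center)

    def as_array(self) -> np.ndarray:
        """(5, 3) array in (anterior, posterior, left, right, center) order."""
        return np.stack([p.as_array() for p in self.points()])


@dataclass(frozen=True)
class VertebraLandmarks:
    """The 10 landmarks (two endplates) of one vertebra."""

    level: str
    superior: Endplate
    inferior: Endplate

    def body_center(self) -> np.ndarray:
        """Mean of the two endplate centers."""
        return 0.5 * (self.superior.center.as_array() + self.inferior.center.as_array())


@dataclass(frozen=True)
class PelvisLandmarks:
    """Femoral-head centers and S1 superior-endplate landmarks."""

    femoral_head_left: Point3
    femoral_head_right: Point3
    sacral_anterior: Point3
    sacral_posterior: Point3
    sacral_center: Point3

    def hip_axis(self) -> np.ndarray:
        """Midpoint of the two femoral-head centers."""
        return 0.5 * (
            self.femoral_head_left.as_array() + self.femoral_head_right.as_array()
        )


@dataclass
class SpineReconstruction:
    """Ordered landmark model of the thoracolumbar spine + pelvis of one subject."""

    subject_id: str
    age: float
    sex: str
    vertebrae: list[VertebraLandmarks]
    pelvis: PelvisLandmarks
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = [v.level for v in self.vertebrae]
        if sorted(order, key=level_index) != list(LEVELS):
            missing = [lvl for lvl in LEVELS if lvl not in order]
            if missing:
                raise SchemaError(f"missing level {missing[0]}")
            raise SchemaError(f"unexpected vertebra set {order}")
        self.vertebrae = sorted(self.vertebrae, key=lambda v: level_index(v.level))

    def vertebra(self, level: str) -> VertebraLandmarks:
        return self.vertebrae[level_index(level)]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _plane_rms(points: np.ndarray) -> float:
    """RMS residual of the best-fit plane through a (n, 3) point cloud."""
    centered = points - points.mean(axis=0)
    # smallest singular value of the centered cloud = residual norm along normal
    s = np.linalg.svd(centered, compute_uv=False)
    return float(s[-1] / math.sqrt(len(points)))


def validate_reconstruction(
    r: SpineReconstruction, plane_tol: float = 0.3
) -> list[str]:
    """Check every type invariant; return human-readable violations.

    Violations are data, not exceptions: an empty list means the
    reconstruction satisfies the model invariants.  ``plane_tol`` is the
    admissible RMS plane-fit residual of each 5-point endplate in cm
    (noiseless synthetic endplates are exactly planar).
    """
    violations: list[str] = []
    for v in r.vertebrae:
        for name, e in (("superior", v.superior), ("inferior", v.inferior)):
            pts = e.as_array()
            if len(np.unique(pts.round(9), axis=0)) != 5:
                violations.append(f"{v.level} {name}: endplate points not distinct")
            if _plane_rms(pts) > plane_tol:
                violations.append(
                    f"{v.level} {name}: endplate plane-fit RMS exceeds {plane_tol} cm"
                )
            if abs(e.anterior.y - e.posterior.y) < 1e-12:
                violations.append(
                    f"{v.level} {name}: anterior/posterior do not differ in y"
                )
            if abs(e.left.x - e.right.x) < 1e-12:
                violations.append(f"{v.level} {name}: left/right do not differ in x")
        if not v.superior.center.z > v.inferior.center.z:
            violations.append(
                f"{v.level}: superior center not cranial to inferior center"
            )
    centers = np.stack([v.body_center() for v in r.vertebrae])
    dz = np.diff(centers[:, 2])
    for i in np.nonzero(dz >= 0)[0]:
        violations.append(
            f"{LEVELS[i]}/{LEVELS[i + 1]}: body centers not strictly decreasing in z"
        )
    p = r.pelvis
    if np.allclose(
        p.femoral_head_left.as_array(), p.femoral_head_right.as_array()
    ):
        violations.append("pelvis: femoral heads distinct violated")
    if not p.sacral_anterior.y > p.sacral_posterior.y:
        violations.append("pelvis: sacral_anterior not anterior to sacral_posterior")
    seg = np.stack([p.sacral_anterior.as_array(), p.sacral_posterior.as_array()])
    lo, hi = seg.min(axis=0) - 1e-9, seg.max(axis=0) + 1e-9
    c = p.sacral_center.as_array()
    if not (np.all(c >= lo) and np.all(c <= hi)):
        violations.append("pelvis: sacral_center outside the endplate bounding box")
    l5_inf_z = r.vertebra("L5").inferior.center.z
    if not p.sacral_center.z < l5_inf_z:
        violations.append("pelvis: sacral endplate not caudal to L5")
    return violations


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _endplate_to_dict(e: Endplate) -> dict:
    return {k: list(getattr(e, k).as_array()) for k in _ENDPLATE_KEYS}


def _endplate_from_dict(d: dict, where: str) -> Endplate:
    try:
        return Endplate(**{k: Point3.from_array(d[k]) for k in _ENDPLATE_KEYS})
    except KeyError as exc:
        raise SchemaError(f"{where}: missing landmark {exc.args[0]!r}") from None


def _recon_to_dict(r: SpineReconstruction) -> dict:
    return {
        "subject_id": r.subject_id,
        "age": r.age,
        "sex": r.sex,
        "vertebrae": {
            v.level: {
                "superior": _endplate_to_dict(v.superior),
                "inferior": _endplate_to_dict(v.inferior),
            }
            for v in r.vertebrae
        },
        "pelvis": {k: list(getattr(r.pelvis, k).as_array()) for k in _PELVIS_KEYS},
    }


def _recon_from_dict(d: dict) -> SpineReconstruction:
    for key in ("subject_id", "age", "sex", "vertebrae", "pelvis"):
        if key not in d:
            raise SchemaError(f"subject record missing field {key!r}")
    vertebrae = []
    for lvl in LEVELS:
        if lvl not in d["vertebrae"]:
            raise SchemaError(f"missing level {lvl}")
        vd = d["vertebrae"][lvl]
        vertebrae.append(
            VertebraLandmarks(
                level=lvl,
                superior=_endplate_from_dict(vd["superior"], f"{lvl} superior"),
                inferior=_endplate_from_dict(vd["inferior"], f"{lvl} inferior"),
            )
        )
    pd_ = d["pelvis"]
    missing = [k for k in _PELVIS_KEYS if k not in pd_]
    if missing:
        raise SchemaError(f"missing pelvic landmark {missing[0]!r}")
    pelvis = PelvisLandmarks(**{k: Point3.from_array(pd_[k]) for k in _PELVIS_KEYS})
    return SpineReconstruction(
        subject_id=str(d["subject_id"]),
        age=float(d["age"]),
        sex=str(d["sex"]),
        vertebrae=vertebrae,
        pelvis=pelvis,
    )


_CSV_COLUMNS = ("subject_id", "age", "sex", "structure", "landmark", "x", "y", "z")


def _iter_csv_rows(r: SpineReconstruction) -> Iterable[tuple]:
    base = (r.subject_id, r.age, r.sex)
    for v in r.vertebrae:
        for side, e in (("superior", v.superior), ("inferior", v.inferior)):
            for k in _ENDPLATE_KEYS:
                p = getattr(e, k)
                yield base + (v.level, f"{side}_{k}", p.x, p.y, p.z)
    for k in _PELVIS_KEYS:
        p = getattr(r.pelvis, k)
        yield base + ("pelvis", k, p.x, p.y, p.z)


def write_landmarks(
    recons: Sequence[SpineReconstruction], path: str | Path, format: str = "json"
) -> Path:
    """Write reconstructions to ``path`` as JSON or long-format CSV.

    The JSON file has sorted keys so identical inputs produce byte-identical
    files; the round-trip through :func:`read_landmarks` is lossless.
    """
    path = Path(path)
    if format == "json":
        payload = {"subjects": [_recon_to_dict(r) for r in recons]}
        path.write_text(json.dumps(payload, sort_keys=True, indent=1))
    elif format == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_COLUMNS)
            for r in recons:
                w.writerows(_iter_csv_rows(r))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_landmarks(path: str | Path, format: str | None = None) -> list[SpineReconstruction]:
    """Read a landmark file (JSON or long CSV) into validated reconstructions.

    Vertebra order is canonicalized to T1→L5 regardless of file order.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format == "json":
        payload = json.loads(path.read_text())
        return [_recon_from_dict(d) for d in payload.get("subjects", [])]
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    subjects: dict[str, dict] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_CSV_COLUMNS) - set(reader.fieldnames):
            raise SchemaError(f"CSV must have columns {_CSV_COLUMNS}")
        for row in reader:
            sid = row["subject_id"]
            d = subjects.setdefault(
                sid,
                {
                    "subject_id": sid,
                    "age": float(row["age"]),
                    "sex": row["sex"],
                    "vertebrae": {},
                    "pelvis": {},
                },
            )
            xyz = [float(row["x"]), float(row["y"]), float(row["z"])]
            if not all(math.isfinite(c) for c in xyz):
                raise SchemaError(f"non-finite coordinate for subject {sid}")
            if row["structure"] == "pelvis":
                d["pelvis"][row["landmark"]] = xyz
            else:
                side, _, name = row["landmark"].partition("_")
                vd = d["vertebrae"].setdefault(row["structure"], {})
                vd.setdefault(side, {})[name] = xyz
    return [_recon_from_dict(d) for d in subjects.values()]
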