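"""Straight-line muscle trajectories and their two planar angles.

Muscle paths are modelled as straight lines from the femoral (trochanteric)
attachment toward the pelvic/distal attachment, following the straight-line
method of classic hip musculoskeletal models.  Two signed planar angles
characterise a path direction:

* the **frontal angle** — elevation of the frontal-plane projection above
  the body horizontal; negative for a caudomedially descending course;
* the **transverse angle** — deviation of the axial-plane projection from
  the frontal plane; negative for a dorsomedially directed course.

The packaged default attachment maps are a modelling fixture, reverse-
engineered so that the straight-line directions reproduce the published
group-mean angles per muscle and region; they are not anatomical data.
The frontal table stratifies regions ventral/middle/dorsal and the
transverse table cranial/middle/caudal; both stratifications are carried by
three canonical region slots with alias lookup (cranial maps to the ventral
slot, caudal to the dorsal slot), so one attachment pair encodes both
angles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .frames import CANONICAL_FRAME, BodyFrame

__all__ = [
    "MuscleAttachment",
    "TrajectoryRecord",
    "straight_line_direction",
    "frontal_angle",
    "transverse_angle",
    "direction_from_angles",
    "centroid_direction",
    "regional_table",
    "default_attachment_map",
    "table_angle",
    "REGIONS",
    "FRONTAL_ANGLE_TABLE",
    "TRANSVERSE_ANGLE_TABLE",
]

REGIONS = ("ventral", "middle", "dorsal")
_REGION_ALIASES = {"cranial": "ventral", "caudal": "dorsal", **{r: r for r in REGIONS}}
GROUPS = ("pooled", "adult", "juvenile")

_EPS = 1e-12


def canonical_region(region: str) -> str:
    try:
        return _REGION_ALIASES[region]
    except KeyError:
        raise ValueError(f"unknown region {region!r}; expected one of "
                         f"{sorted(_REGION_ALIASES)}") from None


# ---------------------------------------------------------------------------
# Published group-mean trajectory angles (degrees).
#
# Cell order per region: (pooled, adult, juvenile); None marks an empty cell.
# Frontal angles are relative to the body horizontal; transverse angles to
# the frontal plane.  The gluteus maximus is tabulated in two fibre fields
# (cranial and caudal part) in the frontal plane; the combined accessor
# averages the available parts.
# ---------------------------------------------------------------------------

FRONTAL_ANGLE_TABLE: dict[str, dict[str, tuple]] = {
    "gluteus maximus (caudal part)": {
        "middle": (62.46, 65.2, 60.62),
        "dorsal": (66.33, 68.72, 64.38),
    },
    "gluteus maximus (cranial part)": {
        "middle": (50.72, 52.52, 49.4),
        "dorsal": (52.62, 51.95, 53.43),
    },
    "iliotibial band": {
        "middle": (6.48, None, None),
        "dorsal": (8.53, None, None),
    },
    "tensor fasciae latae": {
        # single published row (whole-muscle mean); applies to every region
        "ventral": (19.85, 20.14, 19.35),
        "middle": (19.85, 20.14, 19.35),
        "dorsal": (19.85, 20.14, 19.35),
    },
    "gluteus minimus": {
        "ventral": (32.99, 34.49, 31.76),
        "middle": (43.36, 44.17, 42.42),
    },
    "gluteus medius": {
        "ventral": (22.55, 26.44, 19.57),
        "middle": (33.56, 37.01, 30.29),
        "dorsal": (38.08, 39.21, 34.68),
    },
    "vastus lateralis": {
        "ventral": (-3.9, -3.9, None),
        "middle": (-6.35, -5.46, -7.21),
        "dorsal": (-8.24, -8.39, -8.08),
    },
    "piriformis": {
        "middle": (48.64, 47.12, 49.65),
        "dorsal": (49.2, 48.18, 50.74),
    },
    "triceps coxae": {
        "ventral": (80.43, 84.0, 78.64),
        "middle": (82.29, 84.19, 79.19),
    },
    "obturator externus": {
        "ventral": (-77.9, -79.66, -78.51),
        "middle": (-69.06, -70.34, -68.03),
        "dorsal": (-65.4, -67.3, -62.21),
    },
    "quadratus femoris": {
        "middle": (82.21, 85.64, 76.74),
        "dorsal": (82.72, 86.62, 80.12),
    },
}

# Transverse-plane table; regions are cranial/middle/caudal in the source and
# stored here under the canonical slots (cranial -> ventral, caudal -> dorsal).
TRANSVERSE_ANGLE_TABLE: dict[str, dict[str, tuple]] = {
    "gluteus maximus": {
        "ventral": (-8.56, -8.61, -8.49),
        "middle": (-8.34, -8.41, -8.23),
        "dorsal": (-8.33, -8.79, -7.61),
    },
    "piriformis": {
        "ventral": (22.38, 22.4, 22.33),
        "middle": (22.37, 22.3, 22.49),
        "dorsal": (22.39, 22.36, 22.41),
    },
    "triceps coxae": {
        "middle": (26.95, 27.0, 26.91),
        "dorsal": (25.16, 23.84, 26.91),
    },
    "obturator externus": {
        "middle": (32.64, 30.19, 35.08),
        "dorsal": (31.04, 29.16, 34.42),
    },
    "quadratus femoris": {
        "middle": (-8.09, -7.0, -10.56),
        "dorsal": (-4.86, -4.77, -5.12),
    },
}

_GMAX_PARTS = ("gluteus maximus (caudal part)", "gluteus maximus (cranial part)")

#: Muscles with a packaged default attachment entry.
DEFAULT_MUSCLES = (
    "gluteus maximus",
    "gluteus medius",
    "gluteus minimus",
    "tensor fasciae latae",
    "iliotibial band",
    "vastus lateralis",
    "piriformis",
    "triceps coxae",
    "obturator externus",
    "quadratus femoris",
)


def _group_index(group: str) -> int:
    try:
        return GROUPS.index(group)
    except ValueError:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}") from None


def _cell(table: Mapping[str, Mapping[str, tuple]], muscle: str, region: str,
          gi: int) -> float | None:
    cells = table.get(muscle)
    if cells is None:
        return None
    tup = cells.get(region)
    if tup is None:
        return None
    return tup[gi]


def _muscle_mean(table, muscle, gi) -> float | None:
    vals = [tup[gi] for tup in table.get(muscle, {}).values() if tup[gi] is not None]
    return float(np.mean(vals)) if vals else None


def _lookup(table, muscle, region, group) -> float | None:
    """Table cell with fallbacks: group cell -> group muscle mean -> pooled
    cell -> pooled muscle mean -> None."""
    gi = _group_index(group)
    for probe_gi in (gi, 0) if gi != 0 else (0,):
        v = _cell(table, muscle, region, probe_gi)
        if v is not None:
            return float(v)
        v = _muscle_mean(table, muscle, probe_gi)
        if v is not None:
            return v
    return None


def table_angle(plane: str, muscle: str, region: str, group: str = "pooled",
                fallback: bool = True) -> float | None:
    """Published mean angle for a muscle/region/group, with fallback rules.

    ``plane`` is ``"frontal"`` or ``"transverse"``.  The gluteus maximus is
    resolved as the mean of its tabulated fibre parts in the frontal plane.
    With ``fallback=False`` only the literal table cell is returned.
    """
    region = canonical_region(region)
    if plane == "frontal":
        if muscle == "gluteus maximus":
            vals = [
                (_lookup if fallback else
                 (lambda t, m, r, g: _cell(t, m, r, _group_index(g))))(
                    FRONTAL_ANGLE_TABLE, part, region, group)
                for part in _GMAX_PARTS
            ]
            vals = [v for v in vals if v is not None]
            return float(np.mean(vals)) if vals else None
        table = FRONTAL_ANGLE_TABLE
    elif plane == "transverse":
        table = TRANSVERSE_ANGLE_TABLE
    else:
        raise ValueError(f"unknown plane {plane!r}")
    if fallback:
        return _lookup(table, muscle, region, group)
    return _cell(table, muscle, region, _group_index(group))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuscleAttachment:
    """Origin/insertion pair of one muscle region, points in mm (body frame)."""

    muscle: str
    region: str
    femoral_point: np.ndarray
    pelvic_point: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", canonical_region(self.region))
        f = np.asarray(self.femoral_point, dtype=float)
        p = np.asarray(self.pelvic_point, dtype=float)
        object.__setattr__(self, "femoral_point", f)
        object.__setattr__(self, "pelvic_point", p)
        if np.linalg.norm(p - f) < _EPS:
            raise ValueError(f"{self.muscle}/{self.region}: femoral and pelvic "
                             "attachment points coincide")


@dataclass(frozen=True)
class TrajectoryRecord:
    muscle: str
    region: str
    group: str
    frontal_angle_deg: float
    transverse_angle_deg: float


def straight_line_direction(att: MuscleAttachment) -> np.ndarray:
    """Unit vector from the femoral toward the pelvic attachment point."""
    delta = att.pelvic_point - att.femoral_point
    norm = np.linalg.norm(delta)
    if norm < _EPS:
        raise ValueError("attachment points coincide")
    return delta / norm


def frontal_angle(direction, frame: BodyFrame = CANONICAL_FRAME) -> float:
    """Signed elevation (deg) of the frontal projection above the horizontal.

    Positive when the direction climbs cranially, negative for a caudomedial
    course; range (-90, 90].  Rejects directions orthogonal to the frontal
    plane.
    """
    x, _, z = frame.components(np.asarray(direction, dtype=float))
    if math.hypot(x, z) < 1e-9:
        raise ValueError("direction has no frontal-plane projection")
    return math.degrees(math.atan2(z, abs(x)))


def transverse_angle(direction, frame: BodyFrame = CANONICAL_FRAME) -> float:
    """Signed deviation (deg) of the axial projection from the frontal plane.

    Positive ventrally, negative for a dorsomedial course; range (-90, 90].
    Rejects directions orthogonal to the transverse plane.
    """
    x, y, _ = frame.components(np.asarray(direction, dtype=float))
    if math.hypot(x, y) < 1e-9:
        raise ValueError("direction has no transverse-plane projection")
    return math.degrees(math.atan2(y, abs(x)))


def direction_from_angles(frontal_deg: float, transverse_deg: float,
                          frame: BodyFrame = CANONICAL_FRAME) -> np.ndarray:
    """Unit direction reproducing the two planar angles.

    The pair of angles determines the direction only up to reflection of the
    lateral component; the ambiguity is resolved toward medial (negative
    lateral component), matching a femoral-to-pelvic reading.
    """
    if not (abs(frontal_deg) < 90.0 and abs(transverse_deg) < 90.0):
        raise ValueError("planar angles must lie strictly inside (-90, 90) "
                         "to reconstruct a direction")
    v = (-frame.horizontal_axis
         + math.tan(math.radians(transverse_deg)) * frame.ventral_axis
         + math.tan(math.radians(frontal_deg)) * frame.vertical_axis)
    return v / np.linalg.norm(v)


def centroid_direction(cross_sections: Sequence[np.ndarray]) -> np.ndarray:
    """Direction of the muscle-belly centroid path (endpoint chord).

    ``cross_sections`` is an ordered sequence of planar point sets, one per
    imaging slice through the belly; the centroids are connected and the
    chord from the first to the last centroid, normalised, is returned.  For
    a straight prismatic belly this equals the straight-line direction; for
    a curved belly it is the chord of the curved centroid path.
    """
    if len(cross_sections) < 2:
        raise ValueError("centroid method needs at least two cross-sections")
    centroids = np.array([np.mean(np.asarray(s, dtype=float), axis=0)
                          for s in cross_sections])
    chord = centroids[-1] - centroids[0]
    norm = np.linalg.norm(chord)
    if norm < _EPS:
        raise ValueError("centroid path has zero extent")
    return chord / norm


# ---------------------------------------------------------------------------
# Default attachment maps
# ---------------------------------------------------------------------------

#: Femoral attachment sites (mm): near the trochanter, offset ventro-dorsally
#: per region slot.  Schematic fixture geometry.
_FEMORAL_BASE = np.array([14.0, 0.0, 2.0])
_REGION_OFFSET_MM = {"ventral": 6.0, "middle": 0.0, "dorsal": -6.0}
_DEFAULT_FIBRE_LENGTH_MM = 80.0


def default_attachment_map(group: str = "pooled", scale_mm: float = 1.0,
                           ) -> dict[tuple[str, str], MuscleAttachment]:
    """Packaged attachment-point fixture for a study group.

    Every default muscle gets one attachment pair per region slot whose
    straight-line direction reproduces the published mean angles (with the
    documented fallback rules for empty cells; muscles absent from the
    transverse table run parallel to the frontal plane).
    """
    _group_index(group)
    out: dict[tuple[str, str], MuscleAttachment] = {}
    for muscle in DEFAULT_MUSCLES:
        for region in REGIONS:
            fa = table_angle("frontal", muscle, region, group)
            ta = table_angle("transverse", muscle, region, group)
            fa = 0.0 if fa is None else fa
            ta = 0.0 if ta is None else ta
            d = direction_from_angles(fa, ta)
            femoral = scale_mm * (_FEMORAL_BASE
                                  + np.array([0.0, _REGION_OFFSET_MM[region], 0.0]))
            pelvic = femoral + scale_mm * _DEFAULT_FIBRE_LENGTH_MM * d
            out[(muscle, region)] = MuscleAttachment(muscle, region, femoral, pelvic)
    return out


def regional_table(phantoms, frame: BodyFrame = CANONICAL_FRAME,
                   ) -> list[TrajectoryRecord]:
    """Per muscle x region x group trajectory angles, averaged over a cohort.

    ``phantoms`` is a single phantom or an iterable of phantoms (objects with
    ``attachments`` and ``meta``).  Muscles missing from a member's map are
    skipped with a warning.
    """
    if not isinstance(phantoms, Iterable):
        phantoms = [phantoms]
    phantoms = list(phantoms)
    expected: set[tuple[str, str]] = set()
    for ph in phantoms:
        expected.update((m, r) for (m, r) in ph.attachments)
    by_key: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    for ph in phantoms:
        group = ph.meta.spec.age_group
        for muscle, region in sorted(expected - set(ph.attachments)):
            warnings.warn(f"muscle {muscle!r} region {region!r} missing from an "
                          "attachment map; member omitted from that record",
                          stacklevel=2)
        for (muscle, region), att in ph.attachments.items():
            d = straight_line_direction(att)
            by_key.setdefault((muscle, region, group), []).append(
                (frontal_angle(d, frame), transverse_angle(d, frame)))
    records = []
    for (muscle, region, group), pairs in sorted(by_key.items()):
        arr = np.asarray(pairs)
        records.append(TrajectoryRecord(muscle, region, group,
                                        float(arr[:, 0].mean()),
                                        float(arr[:, 1].mean())))
    return records
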