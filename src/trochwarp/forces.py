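"""Tension-band force model of the trochanteric growth-plate warp.

Three traction systems act on the greater trochanter:

* the **internal** band — gluteus medius, gluteus minimus and vastus
  lateralis, fascially coupled over the trochanter;
* the **external** band — gluteus maximus, tensor fasciae latae and the
  iliotibial band;
* the **posterior** system — the short external rotators (piriformis,
  triceps coxae, obturator externus, quadratus femoris), which attach only
  to the dorsal third and are closed into a band not by an opposing muscle
  but by passive periosteal tension looping over the trochanter tip.

Each muscle contributes a force along its straight-line direction with
magnitude proportional to its physiological cross-sectional area (PCSA);
the specific-tension constant sigma cancels out of every direction and
angle result.  Growth plates align perpendicular to the force acting on
them, so the predicted plate inclination of a region is 90 deg minus the
frontal elevation of that region's force resultant.

The periosteal counterforce is a redirection of the rotator resultant: a
vector of magnitude ``beta * |R|`` pointing caudally, tilted by ``phi``
degrees toward lateral in the frontal plane.  The published account of the
parallelogram is qualitative, so ``phi`` and ``beta`` are free parameters;
their defaults come from a documented one-line calibration (see
:func:`calibrate_counterforce_beta`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .frames import CANONICAL_FRAME, BodyFrame
from .morphometry import ay_angle
from .trajectories import REGIONS, default_attachment_map, straight_line_direction

__all__ = [
    "PCSATable",
    "TensionBandSystem",
    "ForceResolution",
    "pcsa_table",
    "muscle_force_vector",
    "periosteal_counterforce",
    "calibrate_counterforce_beta",
    "predicted_ay_from_resultant",
    "pcsa_group_sum",
    "pcsa_group_ratio",
    "warp_prediction_profile",
    "INTERNAL_BAND",
    "EXTERNAL_BAND",
    "POSTERIOR_SYSTEM",
    "PCSA_SOURCES",
    "GROUP_A_PROXIMAL",
    "GROUP_B_ROTATORS",
    "GROUPED_PCSA_PRINTED",
    "DEFAULT_PHI_DEG",
]

# ---------------------------------------------------------------------------
# Published PCSA values (cm^2) by literature source.  The Brand column's
# obturator-externus entry is printed as 3795 — a decimal-point artifact of
# the source table (plausibly 3.795).  It is stored raw and corrected only
# behind an explicit, flagged option.  Brand gives no quadratus femoris
# value.  Pierrynowski is available only as grouped sums (below).
# ---------------------------------------------------------------------------

_PCSA_RAW: dict[str, dict[str, float]] = {
    "brand": {
        "gluteus maximus": 46.04,
        "tensor fasciae latae": 5.23,
        "gluteus minimus": 25.6,
        "gluteus medius": 47.8,
        "vastus lateralis": 40.445,
        "piriformis": 14.85,
        "triceps coxae": 4.63,
        "obturator externus": 3795.0,
    },
    "klein/horsmann": {
        "gluteus maximus": 71.1,
        "tensor fasciae latae": 8.8,
        "gluteus minimus": 25.5,
        "gluteus medius": 98.7,
        "vastus lateralis": 34.85,
        "piriformis": 8.1,
        "triceps coxae": 33.6,
        "obturator externus": 24.6,
        "quadratus femoris": 14.6,
    },
    "lube": {
        "gluteus maximus": 43.0,
        "tensor fasciae latae": 5.9,
        "gluteus minimus": 16.2,
        "gluteus medius": 34.6,
        "vastus lateralis": 42.6,
        "piriformis": 11.2,
        "triceps coxae": 21.7,
        "obturator externus": 8.2,
        "quadratus femoris": 4.6,
    },
}

#: Suspected decimal-typo entries: (source, muscle) -> corrected value.
PCSA_CORRECTIONS = {("brand", "obturator externus"): 3.795}

PCSA_SOURCES = tuple(_PCSA_RAW)

#: Printed grouped sums and ratios (A: proximally directed muscles,
#: B: external rotators, ratio: 100*B/A as printed).  Only the Lube sums and
#: the Pierrynowski ratio recompute exactly from the per-muscle values; the
#: other printed ratios deviate from 100*B/A of their own printed sums.
GROUPED_PCSA_PRINTED = {
    "brand": (124.6, 33.6, 26.00),
    "klein/horsmann": (204.5, 80.9, 39.50),
    "lube": (99.7, 45.7, 45.70),
    "pierrynowski": (127.2, 52.4, 41.20),
}

INTERNAL_BAND = ("gluteus medius", "gluteus minimus", "vastus lateralis")
EXTERNAL_BAND = ("gluteus maximus", "tensor fasciae latae", "iliotibial band")
POSTERIOR_SYSTEM = ("piriformis", "triceps coxae", "obturator externus",
                    "quadratus femoris")

# Grouping of the published PCSA comparison: A pulls proximally from the
# trochanter, B are the external rotators.  The source table names
# "obt. int." in group B, but only obturator externus (a tabulated PCSA
# column) makes the Lube sum consistent; the numerically consistent reading
# is used and flagged here.
GROUP_A_PROXIMAL = ("gluteus maximus", "gluteus medius", "gluteus minimus",
                    "tensor fasciae latae")
GROUP_B_ROTATORS = POSTERIOR_SYSTEM

DEFAULT_PHI_DEG = 60.0


@dataclass(frozen=True)
class PCSATable:
    """Per-muscle physiological cross-sectional areas of one source."""

    source: str
    areas_cm2: Mapping[str, float]
    corrections_applied: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.areas_cm2.values()):
            raise ValueError("PCSA areas must be positive")

    def get(self, muscle: str) -> float | None:
        return self.areas_cm2.get(muscle)


def pcsa_table(source: str, corrected: bool = True) -> PCSATable:
    """PCSA table for a literature source.

    ``corrected=True`` (default) replaces flagged decimal-typo entries by
    their corrected values and records the substitution on the table;
    ``corrected=False`` returns the values exactly as printed.
    """
    key = source.lower()
    if key not in _PCSA_RAW:
        raise ValueError(f"unknown PCSA source {source!r}; "
                         f"available: {', '.join(PCSA_SOURCES)}")
    areas = dict(_PCSA_RAW[key])
    applied = []
    if corrected:
        for (src, muscle), value in PCSA_CORRECTIONS.items():
            if src == key and muscle in areas:
                areas[muscle] = value
                applied.append((muscle, value))
    return PCSATable(key, areas, tuple(applied))


@dataclass(frozen=True)
class TensionBandSystem:
    name: str
    members: tuple[str, ...]
    has_periosteal_counterforce: bool = False


def default_systems() -> dict[str, TensionBandSystem]:
    return {
        "internal": TensionBandSystem("internal", INTERNAL_BAND),
        "external": TensionBandSystem("external", EXTERNAL_BAND),
        "posterior": TensionBandSystem("posterior", POSTERIOR_SYSTEM,
                                       has_periosteal_counterforce=True),
    }


@dataclass(frozen=True)
class ForceResolution:
    """Resolved force state of one plate region."""

    region: str
    member_vectors: Mapping[str, np.ndarray]
    counterforce: np.ndarray | None
    resultant: np.ndarray
    predicted_ay_deg: float


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def muscle_force_vector(direction, pcsa_cm2: float, sigma: float = 1.0) -> np.ndarray:
    """Force vector sigma * PCSA * direction (arbitrary force units)."""
    if pcsa_cm2 <= 0:
        raise ValueError("PCSA must be positive")
    if sigma <= 0:
        raise ValueError("specific tension must be positive")
    d = np.asarray(direction, dtype=float)
    return sigma * pcsa_cm2 * d


def periosteal_counterforce(
    rotator_resultant,
    phi_deg: float = DEFAULT_PHI_DEG,
    beta: float | None = None,
    frame: BodyFrame = CANONICAL_FRAME,
) -> np.ndarray:
    """Passive periosteal reaction to the rotator pull.

    A vector of magnitude ``beta * |rotator_resultant|`` directed caudally
    and tilted ``phi_deg`` toward lateral in the frontal plane (toward the
    side opposing the rotators' medial pull).  ``beta=None`` invokes the
    default calibration (:func:`calibrate_counterforce_beta`), which zeroes
    the lateral component of the posterior resultant so the redirected
    force is frontally vertical.
    """
    r = np.asarray(rotator_resultant, dtype=float)
    mag = np.linalg.norm(r)
    if mag < 1e-12:
        raise ValueError("rotator resultant is zero; no counterforce defined")
    if beta is None:
        beta = calibrate_counterforce_beta(r, phi_deg, frame)
    if beta < 0:
        raise ValueError("beta must be non-negative")
    x, _, _ = frame.components(r)
    lateral_sign = -1.0 if x > 0 else 1.0  # oppose the rotators' frontal pull
    phi = math.radians(phi_deg)
    direction = (lateral_sign * math.sin(phi) * frame.horizontal_axis
                 - math.cos(phi) * frame.vertical_axis)
    return beta * mag * direction


def calibrate_counterforce_beta(
    rotator_resultant,
    phi_deg: float = DEFAULT_PHI_DEG,
    frame: BodyFrame = CANONICAL_FRAME,
) -> float:
    """Beta making the posterior parallelogram resultant frontally vertical.

    The counterforce's lateral component is set to cancel the rotator
    resultant's: ``beta* = |R_lateral| / (|R| sin(phi))``.  For the
    redirected resultant to stay cranially directed, ``phi`` must exceed
    the rotator resultant's frontal deviation from vertical (about 28-44
    deg across the packaged PCSA sources); the default ``phi`` = 60 deg
    satisfies this with margin.
    """
    r = np.asarray(rotator_resultant, dtype=float)
    mag = np.linalg.norm(r)
    if mag < 1e-12:
        raise ValueError("rotator resultant is zero")
    s = math.sin(math.radians(phi_deg))
    if s < 1e-9:
        raise ValueError("phi must be positive to calibrate beta")
    x, _, _ = frame.components(r)
    return abs(x) / (mag * s)


def predicted_ay_from_resultant(resultant, frame: BodyFrame = CANONICAL_FRAME) -> float:
    """Plate inclination (deg) predicted by force-perpendicular alignment.

    90 minus the unsigned frontal elevation of the resultant; a vertical
    resultant predicts a horizontal plate (0 deg), a horizontal resultant a
    vertical plate (90 deg).
    """
    r = np.asarray(resultant, dtype=float)
    elevation = ay_angle(r, frame)  # rejects zero frontal projection
    return 90.0 - elevation


def pcsa_group_sum(table: PCSATable, group: str) -> float:
    """Sum of member areas for group ``A_proximal`` or ``B_rotators``.

    Raises a KeyError naming the first member missing from the table.
    """
    members = {"A_proximal": GROUP_A_PROXIMAL, "B_rotators": GROUP_B_ROTATORS}
    try:
        muscles = members[group]
    except KeyError:
        raise ValueError(f"unknown PCSA group {group!r}; expected "
                         "'A_proximal' or 'B_rotators'") from None
    total = 0.0
    for m in muscles:
        area = table.get(m)
        if area is None:
            raise KeyError(f"PCSA source {table.source!r} has no value for "
                           f"{m!r}; cannot form group {group}")
        total += area
    return total


def pcsa_group_ratio(a_sum: float, b_sum: float) -> float:
    """Rotator-to-proximal area ratio, 100 * B / A (percent)."""
    if a_sum <= 0:
        raise ValueError("group A sum must be positive")
    return 100.0 * b_sum / a_sum


# ---------------------------------------------------------------------------
# Regional assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceModelConfig:
    """Tunable force-model parameters.

    ``itb_area_cm2`` / ``fascial_area_cm2`` are equivalent-area terms for
    the iliotibial band and for the fascial coupling of the vasti — forces
    the source tables cannot quantify — and default to zero.  ``beta=None``
    selects the calibrated counterforce gain.
    """

    pcsa_source: str = "lube"
    phi_deg: float = DEFAULT_PHI_DEG
    beta: float | None = None
    itb_area_cm2: float = 0.0
    fascial_area_cm2: float = 0.0
    sigma: float = 1.0
    corrected_pcsa: bool = True
    posterior_weight: float = 1.0


def _member_area(table: PCSATable, muscle: str, config: ForceModelConfig) -> float:
    if muscle == "iliotibial band":
        return config.itb_area_cm2
    area = table.get(muscle)
    if area is None:
        warnings.warn(f"PCSA source {table.source!r} lacks {muscle!r}; "
                      "contributing zero force", stacklevel=3)
        return 0.0
    if muscle == "vastus lateralis":
        # unquantifiable fascial coupling of the other vasti, default 0
        area += config.fascial_area_cm2
    return area


def _directions_for(attachments, members, region, frame) -> dict[str, np.ndarray]:
    missing = [m for m in members if (m, region) not in attachments]
    if missing:
        raise KeyError("attachment map lacks required muscles for region "
                       f"{region!r}: {', '.join(sorted(missing))}")
    return {m: straight_line_direction(attachments[(m, region)]) for m in members}


def warp_prediction_profile(
    attachments: Mapping[tuple[str, str], "object"] | None = None,
    config: ForceModelConfig | None = None,
    frame: BodyFrame = CANONICAL_FRAME,
    group: str = "pooled",
) -> dict[str, ForceResolution]:
    """Predicted plate inclination per region from the acting systems.

    Ventral and middle regions are loaded by the lateral (internal +
    external) bands at their region-specific directions.  The dorsal region
    carries the lateral bands' mid-region resultant unchanged — the source
    trajectory tables have no dorsal entries for several lateral-band
    members, and the model attributes all dorsal-specific change to the
    posterior system — plus the PCSA-weighted rotators at their dorsal
    directions and the periosteal counterforce.  Setting the rotators'
    weight to zero therefore reduces the dorsal prediction exactly to the
    middle one.
    """
    config = config or ForceModelConfig()
    if attachments is None:
        attachments = default_attachment_map(group)
    table = pcsa_table(config.pcsa_source, corrected=config.corrected_pcsa)
    lateral = INTERNAL_BAND + EXTERNAL_BAND

    def member_vectors(members, region, weight=1.0):
        dirs = _directions_for(attachments, members, region, frame)
        out = {}
        for m, d in dirs.items():
            scaled = weight * _member_area(table, m, config)
            if scaled > 0:
                out[m] = muscle_force_vector(d, scaled, config.sigma)
        return out

    resolutions: dict[str, ForceResolution] = {}
    lateral_mid = member_vectors(lateral, "middle")

    for region in REGIONS:
        if region == "dorsal":
            vectors = dict(lateral_mid)
            rot = member_vectors(POSTERIOR_SYSTEM, "dorsal",
                                 weight=config.posterior_weight)
            vectors.update(rot)
            counter = None
            if rot:
                rot_resultant = np.sum(list(rot.values()), axis=0)
                if np.linalg.norm(rot_resultant) > 1e-12:
                    counter = periosteal_counterforce(
                        rot_resultant, config.phi_deg, config.beta, frame)
        else:
            vectors = member_vectors(lateral, region)
            counter = None
        resultant = np.sum(list(vectors.values()), axis=0)
        if counter is not None:
            resultant = resultant + counter
        resolutions[region] = ForceResolution(
            region=region,
            member_vectors=vectors,
            counterforce=counter,
            resultant=resultant,
            predicted_ay_deg=predicted_ay_from_resultant(resultant, frame),
        )
    return resolutions


def posterior_system_resolution(
    attachments=None,
    config: ForceModelConfig | None = None,
    frame: BodyFrame = CANONICAL_FRAME,
    group: str = "pooled",
) -> ForceResolution:
    """The posterior parallelogram alone: rotator pull plus counterforce.

    This is the dorsal trochanteric force vector of the tension-band
    account — with the calibrated default gain its frontal projection is
    vertical, i.e. "almost vertical" orientation and a near-horizontal
    predicted plate.
    """
    config = config or ForceModelConfig()
    if attachments is None:
        attachments = default_attachment_map(group)
    table = pcsa_table(config.pcsa_source, corrected=config.corrected_pcsa)
    dirs = _directions_for(attachments, POSTERIOR_SYSTEM, "dorsal", frame)
    vectors = {}
    for m, d in dirs.items():
        area = _member_area(table, m, config)
        if area > 0:
            vectors[m] = muscle_force_vector(d, config.posterior_weight * area,
                                             config.sigma)
    if not vectors:
        raise ValueError("posterior system has no force-bearing members")
    rot = np.sum(list(vectors.values()), axis=0)
    counter = periosteal_counterforce(rot, config.phi_deg, config.beta, frame)
    resultant = rot + counter
    return ForceResolution("dorsal", vectors, counter, resultant,
                           predicted_ay_from_resultant(resultant, frame))


def frontal_elevation(vector, frame: BodyFrame = CANONICAL_FRAME) -> float:
    """Unsigned frontal elevation (deg) of a vector — 90 means vertical."""
    return ay_angle(vector, frame)
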