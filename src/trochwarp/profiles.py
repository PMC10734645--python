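"""Per-layer inclination profiles of the trochanteric apophyseal plate.

A :class:`WarpProfile` holds twelve angles (degrees to the body horizontal),
one per frontal slice layer, ordered ventral (layer 1) to dorsal (layer 12).
The default profiles are not raw data: the individual layer means were never
published, only summary anchors (thirds means, the calibration-layer angle,
the ventral rise, the total ventro-dorsal decrease and the position of the
transition jump).  :func:`solve_warp_profile` reconstructs a twelve-layer
profile that satisfies those anchors exactly, by a fixed interpolation rule
documented below, and the results are frozen as package constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "WarpProfile",
    "solve_warp_profile",
    "build_default_warp_profile",
    "POOLED_WARP_ANGLES",
    "JUVENILE_WARP_ANGLES",
]

N_LAYERS = 12

#: Thirds partition of the twelve frontal layers (1-based labels).
VENTRAL_LAYERS = (1, 2, 3, 4)
MIDDLE_LAYERS = (5, 6, 7, 8)
DORSAL_LAYERS = (9, 10, 11, 12)


@dataclass(frozen=True)
class WarpProfile:
    """Twelve per-layer plate inclination angles, ventral to dorsal.

    Angles are in degrees relative to the body horizontal and must lie in
    [0, 90].  Index 0 of ``angles_deg`` is the most ventral layer (label 1),
    index 11 the most dorsal (label 12).
    """

    angles_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles_deg)
        if len(angles) != N_LAYERS:
            raise ValueError(f"warp profile needs {N_LAYERS} layers, got {len(angles)}")
        if any(not (0.0 <= a <= 90.0) for a in angles):
            raise ValueError("warp angles must lie in [0, 90] degrees")
        object.__setattr__(self, "angles_deg", angles)

    def __getitem__(self, layer: int) -> float:
        """Angle of 1-based layer label ``layer``."""
        if not 1 <= layer <= N_LAYERS:
            raise IndexError(f"layer label must be in 1..{N_LAYERS}")
        return self.angles_deg[layer - 1]

    @property
    def total_decrease(self) -> float:
        """Layer-1 minus layer-12 angle (ventro-dorsal decrease)."""
        return self.angles_deg[0] - self.angles_deg[-1]

    def third_mean(self, layers: Iterable[int]) -> float:
        return float(np.mean([self[k] for k in layers]))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.angles_deg, dtype=float)


def solve_warp_profile(
    ventral_third_mean: float = 51.64,
    dorsal_third_mean: float = 18.6,
    calibration_angle: float = 43.7,
    ventral_rise: float = 2.0,
    total_decrease: float = 33.44,
    dorsal_slope: float = 0.4,
) -> WarpProfile:
    """Reconstruct a twelve-layer profile from published summary anchors.

    The system is under-determined (six constraints, twelve unknowns); the
    remaining freedom is closed by a fixed interpolation rule:

    1. The dorsal third (layers 9-12) is an arithmetic ramp of gentle slope
       ``dorsal_slope`` (deg/layer, descending) centred on its mean — the
       profile is described as stable past the transition zone.
    2. Layer 1 follows from layer 12 and the total decrease; layer 2 sits
       ``ventral_rise`` above layer 1.
    3. Layers 3-4 continue an arithmetic descent from layer 2 whose step is
       solved so the ventral-third mean is met exactly.
    4. Layer 5 is midway between layer 4 and the calibration layer 6; layers
       7-8 continue the same mid-third slope past layer 6.

    The resulting profile places its largest inter-layer drop between layers
    8 and 9 (the transition zone) and is non-increasing from layer 2 on.
    A :class:`ValueError` is raised if the requested anchors cannot be met
    under this rule (range violation, lost monotonicity, or a transition
    jump that is not the maximal drop).
    """
    a = np.empty(N_LAYERS)
    # dorsal ramp around its mean: offsets +1.5s, +0.5s, -0.5s, -1.5s
    a[8:12] = dorsal_third_mean + dorsal_slope * np.array([1.5, 0.5, -0.5, -1.5])
    a[0] = a[11] + total_decrease
    a[1] = a[0] + ventral_rise
    # a3, a4 arithmetic from a2 with step d: a1 + 3*a2 - 3d = 4 * ventral mean
    d = (a[0] + 3.0 * a[1] - 4.0 * ventral_third_mean) / 3.0
    a[2] = a[1] - d
    a[3] = a[1] - 2.0 * d
    a[5] = calibration_angle
    a[4] = 0.5 * (a[3] + a[5])
    g = 0.5 * (a[5] - a[3])  # mid-third per-layer slope (negative)
    a[6] = a[5] + g
    a[7] = a[5] + 2.0 * g

    profile = WarpProfile(tuple(a))
    _audit(profile, ventral_third_mean, dorsal_third_mean, calibration_angle,
           ventral_rise, total_decrease)
    return profile


def _audit(profile, ventral_mean, dorsal_mean, calibration, rise, decrease,
           tol: float = 1e-9) -> None:
    a = profile.as_array()
    checks = {
        "ventral third mean": abs(a[0:4].mean() - ventral_mean),
        "dorsal third mean": abs(a[8:12].mean() - dorsal_mean),
        "calibration angle": abs(a[5] - calibration),
        "ventral rise": abs((a[1] - a[0]) - rise),
        "total decrease": abs((a[0] - a[11]) - decrease),
    }
    for name, err in checks.items():
        if err > tol:
            raise ValueError(f"profile reconstruction failed: {name} off by {err:g}")
    if np.any(np.diff(a[1:]) > tol):
        raise ValueError("profile reconstruction failed: layers 2..12 not non-increasing")
    drops = np.abs(np.diff(a[1:]))  # consecutive differences among layers 2..12
    if int(np.argmax(drops)) != 6:  # pairs (2,3)..(11,12); index 6 is (8,9)
        raise ValueError("profile reconstruction failed: max drop not between layers 8 and 9")


# Frozen outputs of solve_warp_profile with the default (pooled) anchors and
# with the juvenile anchors (total decrease 8 deg smaller, dorsal third lifted
# by the same amount so the ventral third is shared between age groups).
POOLED_WARP_ANGLES: tuple[float, ...] = (
    51.44, 53.44,
    51.706666666666667, 49.973333333333333,
    46.836666666666666, 43.7, 40.56333333333333, 37.42666666666667,
    19.2, 18.8, 18.4, 18.0,
)
JUVENILE_WARP_ANGLES: tuple[float, ...] = (
    51.44, 53.44,
    51.706666666666667, 49.973333333333333,
    46.836666666666666, 43.7, 40.56333333333333, 37.42666666666667,
    27.2, 26.8, 26.4, 26.0,
)

#: Juvenile total decrease is set 8 deg below the adult/pooled value; the
#: pediatric layers flatten less toward dorsal while the ventral third matches.
JUVENILE_DECREASE_OFFSET = 8.0


def build_default_warp_profile(
    group: Literal["juvenile", "adult", "pooled"] = "pooled",
) -> WarpProfile:
    """Default per-layer profile for a study group.

    ``pooled`` and ``adult`` return the profile reconstructed from the pooled
    summary anchors (the published cohort is summarised pooled; the adult
    subgroup shows the full decrease).  ``juvenile`` shares the ventral
    anchors but has a total decrease smaller by ``JUVENILE_DECREASE_OFFSET``.
    """
    if group in ("pooled", "adult"):
        return WarpProfile(POOLED_WARP_ANGLES)
    if group == "juvenile":
        return WarpProfile(JUVENILE_WARP_ANGLES)
    raise ValueError(f"unknown group {group!r}; expected juvenile/adult/pooled")


def solve_default_profile(group: str = "pooled") -> WarpProfile:
    """Re-run the constraint procedure that produced the frozen constants."""
    if group in ("pooled", "adult"):
        return solve_warp_profile()
    if group == "juvenile":
        return solve_warp_profile(
            dorsal_third_mean=18.6 + JUVENILE_DECREASE_OFFSET,
            total_decrease=33.44 - JUVENILE_DECREASE_OFFSET,
        )
    raise ValueError(f"unknown group {group!r}")
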