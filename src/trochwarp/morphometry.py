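"""AY-angle measurement and profile statistics.

The AY angle of a frontal layer is the acute angle between the plate trace
in that slice and the body horizontal axis, in [0, 90] degrees.  This module
chains the measurement protocol — slice, select the calibration layer, fit
a line to each trace, take its frontal elevation — and summarises the
resulting per-layer profile (thirds means, calibration angle, total
ventro-dorsal decrease, transition zone) and group contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .frames import BodyFrame, build_body_frame
from .phantom import Phantom
from .profiles import DORSAL_LAYERS, MIDDLE_LAYERS, N_LAYERS, VENTRAL_LAYERS
from .slicing import label_map, slice_phantom

__all__ = [
    "AYProfile",
    "ProfileSummary",
    "GroupComparison",
    "fit_plate_line",
    "ay_angle",
    "measure_profile",
    "summarize_profile",
    "compare_groups",
]


@dataclass(frozen=True)
class AYProfile:
    """Measured AY angles by layer label (1..12) for one subject."""

    patient_id: str
    angles_deg: Mapping[int, float]
    group: str = "pooled"

    def __post_init__(self) -> None:
        for k, a in self.angles_deg.items():
            if not (0.0 <= a <= 90.0):
                raise ValueError(f"AY angle {a} of layer {k} outside [0, 90]")

    def layer_array(self) -> np.ndarray:
        """Angles for layers 1..12; NaN where missing."""
        out = np.full(N_LAYERS, np.nan)
        for k, a in self.angles_deg.items():
            out[k - 1] = a
        return out


@dataclass(frozen=True)
class ProfileSummary:
    """Summary statistics of one AY profile; absent fields are None.

    Thirds partition the layers 1-4 (ventral), 5-8 (middle), 9-12 (dorsal);
    ``total_decrease`` is the layer-1 minus layer-12 angle; the transition
    pair is the consecutive-layer pair with the largest absolute angle
    change among layers 2..12 (the ventral rise between layers 1 and 2 is
    excluded from transition detection by design).
    """

    ventral_third_mean: float | None
    middle_third_mean: float | None
    dorsal_third_mean: float | None
    calibration_angle: float | None
    total_decrease: float | None
    transition_pair: tuple[int, int] | None


def fit_plate_line(trace: np.ndarray) -> np.ndarray:
    """Total-least-squares line direction of a planar trace.

    Returns the unit direction of the first principal axis of the centred
    points, oriented with positive lateral (x) component (positive cranial
    component where the lateral component vanishes).  For a perfectly
    symmetric V-shaped trace the first principal axis is orthogonal to the
    symmetry axis — the fit bisects the V, which is the documented
    degenerate-case behaviour.  All-coincident points are rejected.
    """
    pts = np.asarray(trace, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("line fit needs at least two points")
    centered = pts - pts.mean(axis=0)
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12:
        raise ValueError("all trace points coincide; no line direction")
    d = vt[0]
    if abs(d[0]) > 1e-12:
        d = d * np.sign(d[0])
    elif abs(d[2]) > 1e-12:
        d = d * np.sign(d[2])
    return d


def ay_angle(direction, frame: BodyFrame) -> float:
    """Acute angle (deg, in [0, 90]) between a direction's frontal-plane
    projection and the frame's horizontal axis.

    Invariant under translation and uniform scaling of the measured scene;
    rejects directions orthogonal to the frontal plane.
    """
    x, _, z = frame.components(np.asarray(direction, dtype=float))
    if math.hypot(x, z) < 1e-9:
        raise ValueError("direction has no frontal-plane projection")
    return math.degrees(math.atan2(abs(z), abs(x)))


def measure_profile(
    phantom: Phantom,
    frame: BodyFrame | None = None,
    thickness_mm: float | None = None,
    n_points: int = 25,
    noise_sd_mm: float | None = None,
) -> AYProfile:
    """End-to-end AY measurement of one phantom.

    Slices frontally, locates the calibration slice, labels layers, fits a
    line to each plate trace and takes its AY angle in the body frame built
    from the phantom's landmarks (or an explicit ``frame``).
    """
    if frame is None:
        frame = build_body_frame(phantom.landmarks["sacral_center"],
                                 phantom.landmarks["anus_center"])
    stack = slice_phantom(phantom, "frontal", thickness_mm=thickness_mm,
                          n_points=n_points, noise_sd_mm=noise_sd_mm)
    angles: dict[int, float] = {}
    for label, idx in sorted(label_map(stack).items()):
        direction = fit_plate_line(stack.traces[idx])
        angles[label] = ay_angle(direction, frame)
    return AYProfile(patient_id=f"phantom-{phantom.seed}", angles_deg=angles,
                     group=phantom.meta.spec.age_group)


def _mean_if_complete(angles: Mapping[int, float], layers) -> float | None:
    if all(k in angles for k in layers):
        return float(np.mean([angles[k] for k in layers]))
    return None


def summarize_profile(profile: AYProfile) -> ProfileSummary:
    """Thirds means, calibration angle, total decrease and transition zone.

    Layers missing from the profile leave the affected fields None (partial
    summary) rather than raising.
    """
    a = profile.angles_deg
    transition = None
    diffs = [(abs(a[k + 1] - a[k]), k) for k in range(2, N_LAYERS)
             if k in a and (k + 1) in a]
    if diffs:
        _, k = max(diffs, key=lambda t: (t[0], -t[1]))
        transition = (k, k + 1)
    return ProfileSummary(
        ventral_third_mean=_mean_if_complete(a, VENTRAL_LAYERS),
        middle_third_mean=_mean_if_complete(a, MIDDLE_LAYERS),
        dorsal_third_mean=_mean_if_complete(a, DORSAL_LAYERS),
        calibration_angle=a.get(6),
        total_decrease=(a[1] - a[12]) if (1 in a and 12 in a) else None,
        transition_pair=transition,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Juvenile-vs-adult contrast of AY profiles.

    ``decrease_difference`` is the adult minus juvenile mean total decrease
    (positive when the adult plate flattens more dorsally), with a seeded
    patient-level percentile bootstrap interval.  Fields involving an empty
    group are None.
    """

    layer_means: dict[str, np.ndarray]
    group_summaries: dict[str, ProfileSummary]
    n_by_group: dict[str, int]
    decrease_difference: float | None
    ci_low: float | None
    ci_high: float | None
    n_bootstrap: int


def _group_mean_profile(profiles: Sequence[AYProfile]) -> np.ndarray:
    stacked = np.vstack([p.layer_array() for p in profiles])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


def compare_groups(
    profiles: Sequence[AYProfile],
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> GroupComparison:
    """Per-group layer means and the bootstrapped decrease difference.

    Patients are resampled with replacement within each group; the interval
    is the percentile interval of the resampled mean difference.  With a
    single group present the contrast fields are None.
    """
    by_group: dict[str, list[AYProfile]] = {}
    for p in profiles:
        by_group.setdefault(p.group, []).append(p)
    if not by_group:
        raise ValueError("no profiles supplied")

    layer_means = {g: _group_mean_profile(ps) for g, ps in by_group.items()}
    summaries = {
        g: summarize_profile(AYProfile(
            patient_id=f"group-mean-{g}",
            angles_deg={k + 1: m[k] for k in range(N_LAYERS) if np.isfinite(m[k])},
            group=g))
        for g, m in layer_means.items()
    }
    n_by_group = {g: len(ps) for g, ps in by_group.items()}

    diff = lo = hi = None
    if "juvenile" in by_group and "adult" in by_group:
        def decreases(ps):
            vals = [summarize_profile(p).total_decrease for p in ps]
            return np.array([v for v in vals if v is not None])

        juv, adu = decreases(by_group["juvenile"]), decreases(by_group["adult"])
        if len(juv) and len(adu):
            diff = float(adu.mean() - juv.mean())
            rng = np.random.default_rng(seed)
            reps = np.empty(n_bootstrap)
            for b in range(n_bootstrap):
                reps[b] = (adu[rng.integers(0, len(adu), len(adu))].mean()
                           - juv[rng.integers(0, len(juv), len(juv))].mean())
            alpha = 0.5 * (1.0 - ci_level)
            lo, hi = (float(np.quantile(reps, alpha)),
                      float(np.quantile(reps, 1.0 - alpha)))

    return GroupComparison(layer_means, summaries, n_by_group, diff, lo, hi,
                           n_bootstrap)
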