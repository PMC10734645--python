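"""Synthetic proximal-femur phantoms and cohorts.

A phantom is a schematic 3-D stand-in for the imaged anatomy: a ruled
apophyseal-plate surface whose per-layer inclination follows a prescribed
:class:`~trochwarp.profiles.WarpProfile`, an ellipsoidal greater-trochanter
body for axial slicing, midline body landmarks, and per-muscle attachment
point pairs.  Coordinates are mm in the canonical body frame (x lateral,
y ventral, z cranial).

The geometry is deliberately minimal — it emulates what the measurement
pipeline consumes (slice traces, landmarks, attachment points), not image
intensities.  Everything is deterministic in (spec, seed); measurement
noise is realised later, at slicing time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml

from .profiles import N_LAYERS, WarpProfile, build_default_warp_profile
from .trajectories import MuscleAttachment, default_attachment_map

__all__ = [
    "PhantomSpec",
    "Phantom",
    "PlatePatch",
    "CohortSpec",
    "default_phantom_spec",
    "generate_phantom",
    "sample_cohort",
    "save_phantom",
    "load_phantom",
]

AgeGroup = Literal["juvenile", "adult", "pooled"]

# Schematic geometry constants (mm, before the overall scale factor).
_PLATE_CENTER_XZ = (6.0, 10.0)          # frontal-plane position of the plate mid-line
_SEGMENT_LENGTH_PEAK = 30.0             # plate trace length at the calibration layer
# Per-layer decay of trace length.  The taper is steep enough that the
# maximum-extent (calibration) slice stays identifiable under the default
# point noise, as the layer-labelling protocol assumes.
_SEGMENT_LENGTH_FALLOFF = 3.0
_TROCH_CENTER = np.array([16.0, 0.0, 6.0])
_TROCH_SEMIAXES = np.array([11.0, 13.0, 13.5])
_TROCH_CCD_SHIFT = 0.25                 # medial shift of the trochanter per deg of valgus
_SACRAL = np.array([0.0, -60.0, 80.0])
_ANUS = np.array([0.0, -60.0, 0.0])

#: Default neck-shaft angles; coxa valga in the immature skeleton.
DEFAULT_CCD = {"adult": 130.0, "pooled": 130.0, "juvenile": 145.0}
DEFAULT_ANTEVERSION = {"adult": 15.0, "pooled": 15.0, "juvenile": 30.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Generating parameters of one phantom."""

    warp: WarpProfile
    ccd_angle: float = 130.0
    anteversion: float = 15.0
    scale_mm: float = 1.0
    plate_extent_mm: float = 36.0
    age_group: AgeGroup = "pooled"
    attachment_map: Mapping[tuple[str, str], MuscleAttachment] = field(default_factory=dict)
    noise_sd_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (110.0 <= self.ccd_angle <= 160.0):
            raise ValueError(f"CCD angle {self.ccd_angle} outside the plausible "
                             "range [110, 160] deg")
        if self.plate_extent_mm <= 0:
            raise ValueError("plate extent must be positive")
        if self.scale_mm <= 0:
            raise ValueError("scale must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise SD must be non-negative")
        if self.age_group not in ("juvenile", "adult", "pooled"):
            raise ValueError(f"unknown age group {self.age_group!r}")
        # MuscleAttachment itself rejects coincident points; re-check in case
        # the mapping was built from raw arrays.
        for (muscle, region), att in self.attachment_map.items():
            if np.allclose(att.femoral_point, att.pelvic_point):
                raise ValueError(f"degenerate attachment for {muscle}/{region}")


@dataclass(frozen=True)
class PlatePatch:
    """One ruled-surface band of the plate (a quad, stored compactly).

    The band spans ``y_lo <= y < y_hi`` and its trace in any frontal plane
    inside the band is the segment ``center +- t * (cos a, 0, sin a)`` for
    ``|t| <= half_length``, with ``a = angle_deg`` the elevation to the
    horizontal.
    """

    layer: int
    y_lo: float
    y_hi: float
    center_xz: tuple[float, float]
    angle_deg: float
    half_length: float

    def trace_points(self, n_points: int, y: float | None = None) -> np.ndarray:
        """Sample ``n_points`` along the in-plane trace segment."""
        if y is None:
            y = 0.5 * (self.y_lo + self.y_hi)
        a = np.radians(self.angle_deg)
        d = np.array([np.cos(a), 0.0, np.sin(a)])
        c = np.array([self.center_xz[0], y, self.center_xz[1]])
        t = np.linspace(-self.half_length, self.half_length, n_points)
        return c + t[:, None] * d

    @property
    def frontal_elevation_deg(self) -> float:
        return self.angle_deg


@dataclass(frozen=True)
class PhantomMeta:
    spec: PhantomSpec
    seed: int


@dataclass(frozen=True)
class Phantom:
    plate_patches: tuple[PlatePatch, ...]
    landmarks: Mapping[str, np.ndarray]
    attachments: Mapping[tuple[str, str], MuscleAttachment]
    trochanter_center: np.ndarray
    trochanter_semiaxes: np.ndarray
    meta: PhantomMeta

    @property
    def seed(self) -> int:
        return self.meta.seed

    def translated(self, offset) -> "Phantom":
        """Rigidly translated copy (landmarks, patches, attachments)."""
        off = np.asarray(offset, dtype=float)
        patches = tuple(
            replace(p, y_lo=p.y_lo + off[1], y_hi=p.y_hi + off[1],
                    center_xz=(p.center_xz[0] + off[0], p.center_xz[1] + off[2]))
            for p in self.plate_patches)
        landmarks = {k: v + off for k, v in self.landmarks.items()}
        atts = {k: MuscleAttachment(a.muscle, a.region, a.femoral_point + off,
                                    a.pelvic_point + off)
                for k, a in self.attachments.items()}
        return Phantom(patches, landmarks, atts, self.trochanter_center + off,
                       self.trochanter_semiaxes, self.meta)


def default_phantom_spec(group: AgeGroup = "pooled", *, noise_sd_mm: float = 0.0,
                         warp: WarpProfile | None = None,
                         scale_mm: float = 1.0) -> PhantomSpec:
    """Spec with the packaged defaults for a study group."""
    return PhantomSpec(
        warp=warp if warp is not None else build_default_warp_profile(group),
        ccd_angle=DEFAULT_CCD[group],
        anteversion=DEFAULT_ANTEVERSION[group],
        scale_mm=scale_mm,
        age_group=group,
        attachment_map=default_attachment_map(group, scale_mm=scale_mm),
        noise_sd_mm=noise_sd_mm,
    )


def generate_phantom(spec: PhantomSpec, seed: int) -> Phantom:
    """Realise a phantom from its spec; deterministic for fixed (spec, seed).

    The plate patches reproduce ``spec.warp`` exactly (the per-layer frontal
    elevation equals the planted angle, no noise); the seed is carried into
    the phantom and used only when measurement noise is drawn at slicing
    time.
    """
    s = spec.scale_mm
    extent = spec.plate_extent_mm * s
    h = extent / N_LAYERS
    y_ventral = extent / 2.0
    cx, cz = (_PLATE_CENTER_XZ[0] * s, _PLATE_CENTER_XZ[1] * s)
    patches = []
    for k in range(1, N_LAYERS + 1):
        half_len = 0.5 * s * (_SEGMENT_LENGTH_PEAK
                              - _SEGMENT_LENGTH_FALLOFF * abs(k - 6))
        patches.append(PlatePatch(
            layer=k,
            y_lo=y_ventral - k * h,
            y_hi=y_ventral - (k - 1) * h,
            center_xz=(cx, cz),
            angle_deg=spec.warp[k],
            half_length=half_len,
        ))
    # coxa valga moves the trochanter medially relative to the adult default
    troch_center = s * (_TROCH_CENTER
                        - np.array([_TROCH_CCD_SHIFT * (spec.ccd_angle - 130.0), 0, 0]))
    troch_axes = s * _TROCH_SEMIAXES
    landmarks = {
        "sacral_center": s * _SACRAL.copy(),
        "anus_center": s * _ANUS.copy(),
        "trochanter_tip": troch_center + np.array([0.0, 0.0, troch_axes[2]]),
    }
    attachments = dict(spec.attachment_map) or default_attachment_map(
        spec.age_group, scale_mm=s)
    return Phantom(tuple(patches), landmarks, attachments, troch_center,
                   troch_axes, PhantomMeta(spec, int(seed)))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study-cohort generator settings.

    ``noise_sd_mm`` is isotropic Gaussian noise on slice-trace points;
    ``warp_sd_deg`` adds independent per-layer Gaussian variation of the
    planted warp across subjects (between-subject biological variation,
    off by default).  CCD angles are drawn per subject around the group
    default (SD 3 deg), juveniles above the adult distribution.
    """

    n_juvenile: int = 0
    n_adult: int = 0
    noise_sd_mm: float = 0.5
    warp_sd_deg: float = 0.0
    seed: int = 0
    warp_juvenile: WarpProfile | None = None
    warp_adult: WarpProfile | None = None

    def __post_init__(self) -> None:
        if self.n_juvenile < 0 or self.n_adult < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.noise_sd_mm < 0 or self.warp_sd_deg < 0:
            raise ValueError("noise parameters must be non-negative")


_CCD_SD = 3.0


def sample_cohort(cohort: CohortSpec) -> list[Phantom]:
    """Generate the cohort's phantoms, juveniles first, reproducibly.

    Member seeds derive from the master seed by fixed increment
    (``seed + i + 1`` for member i); each member's RNG draws its CCD angle
    and, if ``warp_sd_deg > 0``, its subject-level warp perturbation.
    """
    phantoms: list[Phantom] = []
    groups = [("juvenile", cohort.n_juvenile,
               cohort.warp_juvenile or build_default_warp_profile("juvenile")),
              ("adult", cohort.n_adult,
               cohort.warp_adult or build_default_warp_profile("adult"))]
    i = 0
    for group, n, base_warp in groups:
        for _ in range(n):
            child_seed = int(cohort.seed) + i + 1
            rng = np.random.default_rng(child_seed)
            ccd = float(np.clip(rng.normal(DEFAULT_CCD[group], _CCD_SD), 110.0, 160.0))
            angles = base_warp.as_array()
            if cohort.warp_sd_deg > 0:
                angles = np.clip(angles + rng.normal(0.0, cohort.warp_sd_deg,
                                                     N_LAYERS), 0.0, 90.0)
            spec = PhantomSpec(
                warp=WarpProfile(tuple(angles)),
                ccd_angle=ccd,
                anteversion=DEFAULT_ANTEVERSION[group],
                age_group=group,
                attachment_map=default_attachment_map(group),
                noise_sd_mm=cohort.noise_sd_mm,
            )
            phantoms.append(generate_phantom(spec, child_seed))
            i += 1
    return phantoms


# ---------------------------------------------------------------------------
# Plain-text serialization (one directory per phantom)
# ---------------------------------------------------------------------------

def save_phantom(phantom: Phantom, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = [{"structure": name, "point_role": "landmark",
             "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
            for name, p in phantom.landmarks.items()]
    pd.DataFrame(rows).to_csv(out / "landmarks.tsv", sep="\t", index=False)

    rows = []
    for (muscle, region), att in sorted(phantom.attachments.items()):
        for role, p in (("femoral", att.femoral_point), ("pelvic", att.pelvic_point)):
            rows.append({"structure": muscle, "region": region, "point_role": role,
                         "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]})
    pd.DataFrame(rows).to_csv(out / "attachments.tsv", sep="\t", index=False)

    rows = []
    for p in phantom.plate_patches:
        pts = p.trace_points(2)
        for end, pt in enumerate(pts):
            rows.append({"layer": p.layer, "end": end,
                         "x_mm": pt[0], "y_mm": pt[1], "z_mm": pt[2]})
    pd.DataFrame(rows).to_csv(out / "plate_patches.tsv", sep="\t", index=False)

    spec = phantom.meta.spec
    doc = {
        "seed": phantom.meta.seed,
        "warp_angles_deg": list(spec.warp.angles_deg),
        "ccd_angle": spec.ccd_angle,
        "anteversion": spec.anteversion,
        "scale_mm": spec.scale_mm,
        "plate_extent_mm": spec.plate_extent_mm,
        "age_group": spec.age_group,
        "noise_sd_mm": spec.noise_sd_mm,
        "attachment_map": [
            {"muscle": m, "region": r,
             "femoral": [float(v) for v in a.femoral_point],
             "pelvic": [float(v) for v in a.pelvic_point]}
            for (m, r), a in sorted(phantom.attachments.items())
        ],
    }
    (out / "spec.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
    return out


def load_phantom(in_dir: str | Path) -> Phantom:
    doc = yaml.safe_load((Path(in_dir) / "spec.yaml").read_text())
    att = {(e["muscle"], e["region"]): MuscleAttachment(
        e["muscle"], e["region"], np.array(e["femoral"]), np.array(e["pelvic"]))
        for e in doc["attachment_map"]}
    spec = PhantomSpec(
        warp=WarpProfile(tuple(doc["warp_angles_deg"])),
        ccd_angle=doc["ccd_angle"],
        anteversion=doc["anteversion"],
        scale_mm=doc["scale_mm"],
        plate_extent_mm=doc["plate_extent_mm"],
        age_group=doc["age_group"],
        attachment_map=att,
        noise_sd_mm=doc["noise_sd_mm"],
    )
    return generate_phantom(spec, doc["seed"])
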