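"""Slice-stack extraction and layer labelling.

Emulates the MRI acquisition step: cut a phantom into a stack of frontal
slices (plate traces, ventral to dorsal) or axial slices (trochanter
outlines, cranial to caudal), pick the calibration slice, and assign the
layer labels used to align subjects.

Labelling scheme: the frontal calibration slice (maximum plate-trace
length) is labelled 6, slices v ventral of it 6 - v and d dorsal of it
6 + d; the axial reference slice (maximum trochanter diameter) is
labelled 5, x cranial 5 - x and y caudal 5 + y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .phantom import Phantom

__all__ = [
    "SliceStack",
    "slice_phantom",
    "find_calibration_slice",
    "layer_index",
    "layer_offset",
    "label_map",
]

Orientation = Literal["frontal", "axial"]

FRONTAL_REFERENCE_LABEL = 6
AXIAL_REFERENCE_LABEL = 5
# 12-layer frontal reading: five slices ventral and six dorsal of the
# calibration slice; axial: four cranial and four caudal of the reference.
_OFFSET_RANGE = {"frontal": (-5, 6), "axial": (-4, 4)}

_N_OUTLINE_POINTS = 48
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class SliceStack:
    """Ordered slice traces with the calibration slice identified.

    ``traces[i]`` is an (n, 3) planar polyline; ordering is ventral to
    dorsal for frontal stacks and cranial to caudal for axial stacks.
    ``positions[i]`` is the slice-centre coordinate along the stack normal.
    ``calibration_index`` is the *physical* index of the calibration slice;
    its label is 6 (frontal) or 5 (axial).
    """

    orientation: Orientation
    thickness_mm: float
    traces: tuple[np.ndarray, ...]
    positions: tuple[float, ...]
    calibration_index: int

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")
        if not self.traces:
            raise ValueError("slice stack is empty")

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def reference_label(self) -> int:
        return (FRONTAL_REFERENCE_LABEL if self.orientation == "frontal"
                else AXIAL_REFERENCE_LABEL)

    def labels(self) -> dict[int, int]:
        """Layer label -> physical slice index, for in-range offsets."""
        return label_map(self)


def layer_index(offset_from_reference: int, orientation: Orientation) -> int:
    """Layer label for a signed slice offset from the reference slice.

    Positive offsets run dorsally (frontal) or caudally (axial); the label
    is reference + offset (reference 6 frontal, 5 axial).  Offsets outside
    the stack's labelling range are rejected.
    """
    lo, hi = _offset_range(orientation)
    offset = int(offset_from_reference)
    if not lo <= offset <= hi:
        raise ValueError(f"offset {offset} outside the {orientation} labelling "
                         f"range [{lo}, {hi}]")
    ref = FRONTAL_REFERENCE_LABEL if orientation == "frontal" else AXIAL_REFERENCE_LABEL
    return ref + offset


def layer_offset(label: int, orientation: Orientation) -> int:
    """Inverse of :func:`layer_index`."""
    ref = FRONTAL_REFERENCE_LABEL if orientation == "frontal" else AXIAL_REFERENCE_LABEL
    offset = int(label) - ref
    lo, hi = _offset_range(orientation)
    if not lo <= offset <= hi:
        raise ValueError(f"label {label} outside the {orientation} range")
    return offset


def _offset_range(orientation: Orientation) -> tuple[int, int]:
    try:
        return _OFFSET_RANGE[orientation]
    except KeyError:
        raise ValueError(f"unknown orientation {orientation!r}") from None


def slice_phantom(
    phantom: Phantom,
    orientation: Orientation = "frontal",
    thickness_mm: float | None = None,
    n_points: int = 25,
    noise_sd_mm: float | None = None,
) -> SliceStack:
    """Cut a phantom into a slice stack.

    Frontal slices intersect the plate surface (the trace is the in-plane
    plate segment, projected onto the slice-centre plane); axial slices
    intersect the trochanter ellipsoid (elliptical outlines).  Default
    thickness yields 12 frontal slices over the plate extent, or 9 axial
    slices over the trochanter.  ``noise_sd_mm`` (default: the phantom
    spec's value) adds isotropic Gaussian noise to every trace point, drawn
    from an RNG derived from the phantom seed — identical phantoms produce
    identical stacks.
    """
    if orientation not in ("frontal", "axial"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if noise_sd_mm is None:
        noise_sd_mm = phantom.meta.spec.noise_sd_mm

    if orientation == "frontal":
        traces, positions = _frontal_traces(phantom, thickness_mm, n_points)
        thickness_mm = thickness_mm if thickness_mm is not None else \
            (phantom.plate_patches[0].y_hi - phantom.plate_patches[0].y_lo)
    else:
        traces, positions = _axial_traces(phantom, thickness_mm)
        thickness_mm = thickness_mm if thickness_mm is not None else \
            2.0 * phantom.trochanter_semiaxes[2] / 9.0

    if not traces:
        raise ValueError(f"{orientation} slicing did not intersect the target "
                         "structure (empty stack)")

    if noise_sd_mm > 0:
        rng = np.random.default_rng([phantom.seed,
                                     0 if orientation == "frontal" else 1])
        traces = [t + rng.normal(0.0, noise_sd_mm, t.shape) for t in traces]

    traces = tuple(np.asarray(t) for t in traces)
    stack = SliceStack(orientation, float(thickness_mm), traces,
                       tuple(positions), calibration_index=0)
    cal = find_calibration_slice(stack)
    return SliceStack(orientation, float(thickness_mm), traces,
                      tuple(positions), calibration_index=cal)


def _frontal_traces(phantom, thickness_mm, n_points):
    patches = phantom.plate_patches
    y_top = max(p.y_hi for p in patches)
    y_bot = min(p.y_lo for p in patches)
    extent = y_top - y_bot
    t = extent / 12.0 if thickness_mm is None else float(thickness_mm)
    if t <= 0:
        raise ValueError("slice thickness must be positive")
    n_slices = int(np.floor(extent / t + 1e-9))
    traces, positions = [], []
    for j in range(n_slices):
        hi, lo = y_top - j * t, y_top - (j + 1) * t
        yc = 0.5 * (hi + lo)
        pts = []
        for p in patches:
            if p.y_lo < hi - 1e-12 and p.y_hi > lo + 1e-12:  # band overlaps slice
                pts.append(p.trace_points(n_points, y=yc))
        if pts:
            traces.append(np.vstack(pts))
            positions.append(yc)
    return traces, positions


def _axial_traces(phantom, thickness_mm):
    center = phantom.trochanter_center
    ax, ay, az = phantom.trochanter_semiaxes
    t = 2.0 * az / 9.0 if thickness_mm is None else float(thickness_mm)
    if t <= 0:
        raise ValueError("slice thickness must be positive")
    z_top = center[2] + az
    n_slices = int(np.floor(2.0 * az / t + 1e-9))
    phi = np.linspace(0.0, 2.0 * np.pi, _N_OUTLINE_POINTS, endpoint=False)
    traces, positions = [], []
    for j in range(n_slices):
        zc = z_top - (j + 0.5) * t
        u = (zc - center[2]) / az
        if abs(u) >= 1.0:
            continue
        r = np.sqrt(1.0 - u * u)
        outline = np.column_stack([
            center[0] + ax * r * np.cos(phi),
            center[1] + ay * r * np.sin(phi),
            np.full_like(phi, zc),
        ])
        traces.append(outline)
        positions.append(zc)
    return traces, positions


def find_calibration_slice(stack: SliceStack) -> int:
    """Physical index of the calibration slice.

    Frontal: the slice whose plate trace has maximal longitudinal extent,
    measured as the peak-to-peak extent of the points projected onto the
    trace's total-least-squares line (robust to point noise, equal to the
    polyline arc length for a clean straight trace).  Axial: the slice whose
    trochanter outline has maximal diameter (largest pairwise point
    distance).  Ties within 1e-9 resolve toward the more ventral / cranial
    slice.
    """
    if stack.orientation == "frontal":
        scores = np.array([_line_extent(t) for t in stack.traces])
    else:
        scores = np.array([_diameter(t) for t in stack.traces])
    best = scores.max()
    return int(np.flatnonzero(scores >= best - _TIE_TOL)[0])


def _line_extent(trace: np.ndarray) -> float:
    if len(trace) < 2:
        return 0.0
    centered = trace - trace.mean(axis=0)
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12:
        return 0.0
    proj = centered @ vt[0]
    return float(proj.max() - proj.min())


def _diameter(trace: np.ndarray) -> float:
    if len(trace) < 2:
        return 0.0
    d2 = np.sum((trace[:, None, :] - trace[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def label_map(stack: SliceStack) -> dict[int, int]:
    """Map layer label -> physical slice index for the stack."""
    lo, hi = _offset_range(stack.orientation)
    out = {}
    for i in range(len(stack)):
        offset = i - stack.calibration_index
        if lo <= offset <= hi:
            out[layer_index(offset, stack.orientation)] = i
    return out
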