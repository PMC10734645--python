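"""Body reference frame built from pelvic landmarks.

The vertical body axis is the line through the sacral-vertebrae centre and
the anus centre, read off a dorsal frontal image; the horizontal axis is the
orthogonal direction within that frontal image plane.  Angles downstream
(AY angles, frontal/transverse trajectory angles) are all defined against
this frame, so a tilted patient simply tilts the frame with them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BodyFrame", "build_body_frame", "CANONICAL_FRAME"]

_ORTHO_TOL = 1e-12


@dataclass(frozen=True)
class BodyFrame:
    """Orthonormal body frame.

    ``vertical_axis`` points cranially, ``horizontal_axis`` laterally (toward
    the measured hip) within the frontal plane, ``ventral_axis`` completes the
    right-handed triad (the frontal-plane normal, pointing ventrally).
    """

    vertical_axis: np.ndarray
    horizontal_axis: np.ndarray
    ventral_axis: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        for name in ("vertical_axis", "horizontal_axis", "ventral_axis", "origin"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        v, h, n = self.vertical_axis, self.horizontal_axis, self.ventral_axis
        for axis in (v, h, n):
            if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
                raise ValueError("frame axes must be unit vectors")
        if max(abs(v @ h), abs(v @ n), abs(h @ n)) > 1e-9:
            raise ValueError("frame axes must be orthogonal")

    def components(self, vec: np.ndarray) -> tuple[float, float, float]:
        """(lateral, ventral, cranial) components of ``vec`` in this frame."""
        vec = np.asarray(vec, dtype=float)
        return float(vec @ self.horizontal_axis), float(vec @ self.ventral_axis), float(vec @ self.vertical_axis)


def build_body_frame(
    sacral_center,
    anus_center,
    frontal_normal=(0.0, 1.0, 0.0),
) -> BodyFrame:
    """Construct the body frame from the two midline landmarks.

    ``frontal_normal`` is the normal of the frontal image plane on which the
    landmarks were identified (ventral-pointing); the horizontal axis is the
    in-plane direction orthogonal to the vertical landmark axis.
    """
    sacral = np.asarray(sacral_center, dtype=float)
    anus = np.asarray(anus_center, dtype=float)
    axis = sacral - anus
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("sacral and anus landmarks coincide; cannot build body axis")
    vertical = axis / norm

    normal = np.asarray(frontal_normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("frontal-plane normal must be nonzero")
    normal = normal / nn
    horizontal = np.cross(normal, vertical)
    hn = np.linalg.norm(horizontal)
    if hn < 1e-9:
        raise ValueError("body axis is orthogonal to the frontal plane")
    horizontal = horizontal / hn
    ventral = np.cross(vertical, horizontal)
    ventral = ventral / np.linalg.norm(ventral)
    return BodyFrame(vertical, horizontal, ventral, anus)


#: Frame of the canonical phantom coordinates: x lateral, y ventral, z cranial.
CANONICAL_FRAME = BodyFrame(
    vertical_axis=np.array([0.0, 0.0, 1.0]),
    horizontal_axis=np.array([1.0, 0.0, 0.0]),
    ventral_axis=np.array([0.0, 1.0, 0.0]),
    origin=np.zeros(3),
)
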