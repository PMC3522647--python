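"""Landmark-based affine (shift + shear) registration of breath-hold series.

Transforms act on 0-based voxel coordinates ``(row, col)``. A transform maps
reference coordinates to the moving (breath-hold) frame; aligning a moving
image back onto the reference therefore applies the *inverse* of the
estimated transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError

__all__ = [
    "AffineTransform2D",
    "LandmarkSet",
    "estimate_affine",
    "apply_transform",
]


@dataclass(frozen=True)
class AffineTransform2D:
    """2x2 linear part plus translation, acting as ``p -> L p + t``."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.linear.shape != (2, 2) or self.translation.shape != (2,):
            raise ValidationError("transform must be 2x2 linear + length-2 translation")
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValidationError("linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform2D":
        linv = np.linalg.inv(self.linear)
        return AffineTransform2D(linv, -linv @ self.translation)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Transform equal to applying ``other`` first, then ``self``."""
        return AffineTransform2D(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
        )

    def max_displacement(self, shape: tuple[int, int]) -> float:
        """Largest voxel displacement over an image of the given shape."""
        r, c = shape
        corners = np.array([[0, 0], [0, c - 1], [r - 1, 0], [r - 1, c - 1],
                            [(r - 1) / 2, (c - 1) / 2]], dtype=float)
        d = self.apply_points(corners) - corners
        return float(np.max(np.linalg.norm(d, axis=1)))


@dataclass
class LandmarkSet:
    """Paired (source, target) 2D landmark lists in voxel coordinates."""

    source: np.ndarray
    target: np.ndarray
    hold_index: int = 0

    def __post_init__(self):
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise ValidationError("source and target must be equal-length lists of 2D points")
        if len(self.source) < 3:
            raise ValidationError("at least 3 landmark pairs required for a 2D affine")


def estimate_affine(landmarks: LandmarkSet, model: str = "affine") -> AffineTransform2D:
    """Least-squares affine mapping source landmarks onto target landmarks.

    Exact for 3 non-collinear pairs. ``model`` restricts the class:
    ``"affine"`` (default, shift + shear + scale), ``"translation"``, or
    ``"shear"`` (unit diagonal, free off-diagonals and shift).
    """
    src, dst = landmarks.source, landmarks.target
    if model == "translation":
        return AffineTransform2D(np.eye(2), dst.mean(axis=0) - src.mean(axis=0))
    a = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(a) < 3:
        raise ValidationError("landmarks are collinear; affine is underdetermined")
    sol, *_ = np.linalg.lstsq(a, dst, rcond=None)
    linear = sol[:2].T
    translation = sol[2]
    if model == "shear":
        # re-fit with unit diagonal: dst - src = off-diagonal shear + shift
        d = dst - src
        b = np.hstack([src[:, 1:2], np.ones((len(src), 1))])
        s0, *_ = np.linalg.lstsq(b, d[:, 0], rcond=None)
        b2 = np.hstack([src[:, 0:1], np.ones((len(src), 1))])
        s1, *_ = np.linalg.lstsq(b2, d[:, 1], rcond=None)
        linear = np.array([[1.0, s0[0]], [s1[0], 1.0]])
        translation = np.array([s0[1], s1[1]])
    elif model != "affine":
        raise ValidationError(f"unknown registration model {model!r}")
    return AffineTransform2D(linear, translation)


def apply_transform(image: np.ndarray, transform: AffineTransform2D,
                    order: int = 1) -> np.ndarray:
    """Resample ``image`` under ``transform`` (bilinear by default).

    The output at coordinate ``p`` samples the input at
    ``transform^{-1}(p)``, i.e. features move with the transform.
    Out-of-field voxels are set to 0.
    """
    inv = transform.inverse()
    real = ndimage.affine_transform(
        np.ascontiguousarray(image.real, dtype=float),
        inv.linear, inv.translation, order=order, mode="constant", cval=0.0,
    )
    if not np.iscomplexobj(image):
        return real
    imag = ndimage.affine_transform(
        np.ascontiguousarray(image.imag, dtype=float),
        inv.linear, inv.translation, order=order, mode="constant", cval=0.0,
    )
    return real + 1j * imag


def landmarks_from_transform(transform: AffineTransform2D,
                             points: np.ndarray, hold_index: int = 0) -> LandmarkSet:
    """Landmark pairs generated by a known motion: source in the moved frame,
    target in the reference frame (the direction registration corrects)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return LandmarkSet(source=transform.apply_points(pts), target=pts,
                       hold_index=hold_index)
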