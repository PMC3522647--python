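"""B0 field mapping, volume-selective shim optimization and field statistics.

The field map is the dual-echo phase difference divided by ``2*pi*dTE``;
no spatial unwrapping is performed, so off-resonance beyond the Nyquist
limit ``1/(2*dTE)`` aliases (documented, not corrected). Shimming is a
least-squares fit of the linear + second-order spherical-harmonic basis
over an ROI, subtracted from the map; for 2D maps the z-dependent terms
are dropped, leaving {x, y, x^2-y^2, xy} plus a constant frequency offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import ImageGeometry

__all__ = [
    "FieldMap",
    "ShimSolution",
    "compute_b0_map",
    "fit_shim",
    "field_stats",
    "dispersion_per_voxel",
    "simulate_phase_images",
]

_BASIS_2D_ORDER1 = ("const", "x", "y")
_BASIS_2D_ORDER2 = _BASIS_2D_ORDER1 + ("x2-y2", "xy")


@dataclass
class FieldMap:
    """Per-voxel off-resonance in Hz with its validity mask."""

    dfreq_hz: np.ndarray
    mask: np.ndarray
    dte_ms: float
    geometry: ImageGeometry

    def __post_init__(self):
        if self.dfreq_hz.shape != self.geometry.shape:
            raise ValidationError("field map shape does not match geometry")
        if self.mask.shape != self.dfreq_hz.shape:
            raise ValidationError("mask shape does not match field map")

    @property
    def nyquist_hz(self) -> float:
        """Unambiguous off-resonance range of the phase difference."""
        return 1e3 / (2.0 * self.dte_ms)


@dataclass
class ShimSolution:
    """Fitted shim-basis coefficients and pre/post residual statistics.

    Coefficients are in Hz per mm (linear terms) or Hz per mm^2 (second
    order), with coordinates taken relative to the ROI centroid.
    """

    coefficients: dict[str, float]
    order: int
    roi: np.ndarray
    fitted_surface: np.ndarray
    shimmed_map: "FieldMap"
    pre_stats: dict[str, float]
    post_stats: dict[str, float]


def _wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap to [-pi, pi)."""
    return np.mod(phase + np.pi, 2 * np.pi) - np.pi


def compute_b0_map(phase1: np.ndarray, phase2: np.ndarray,
                   te1_ms: float, te2_ms: float,
                   geometry: ImageGeometry | None = None,
                   mask: np.ndarray | None = None) -> FieldMap:
    """Off-resonance map from two echo phase images (radians).

    ``df = wrap(phi2 - phi1) / (2*pi*(TE2 - TE1))``; with the 1.02 ms echo
    spacing the unambiguous range is +-490.2 Hz.
    """
    if te2_ms <= te1_ms:
        raise ValidationError("TE2 must exceed TE1")
    phase1 = np.asarray(phase1, dtype=float)
    phase2 = np.asarray(phase2, dtype=float)
    if phase1.shape != phase2.shape:
        raise ValidationError("phase images must share a shape")
    dte = te2_ms - te1_ms
    dfreq = _wrap_phase(phase2 - phase1) / (2 * np.pi * dte * 1e-3)
    if geometry is None:
        geometry = ImageGeometry(matrix=phase1.shape,
                                 fov_mm=(float(phase1.shape[0]), float(phase1.shape[1])))
    if mask is None:
        mask = np.ones(phase1.shape, dtype=bool)
    return FieldMap(dfreq_hz=dfreq, mask=np.asarray(mask, dtype=bool),
                    dte_ms=dte, geometry=geometry)


def simulate_phase_images(dfreq_hz: np.ndarray, te1_ms: float, te2_ms: float):
    """Noiseless phase images of an off-resonance field at two echo times,
    wrapped to [-pi, pi). Inverse of ``compute_b0_map`` below Nyquist."""
    p1 = _wrap_phase(2 * np.pi * dfreq_hz * te1_ms * 1e-3)
    p2 = _wrap_phase(2 * np.pi * dfreq_hz * te2_ms * 1e-3)
    return p1, p2


def _basis_matrix(geometry: ImageGeometry, roi: np.ndarray, order: int):
    names = _BASIS_2D_ORDER1 if order == 1 else _BASIS_2D_ORDER2
    yy, xx = geometry.coordinate_grids()
    # centroid-referenced coordinates in mm
    yc = yy[roi] - yy[roi].mean()
    xc = xx[roi] - xx[roi].mean()
    cols = {"const": np.ones_like(xc), "x": xc, "y": yc,
            "x2-y2": xc**2 - yc**2, "xy": xc * yc}
    return np.column_stack([cols[n] for n in names]), names


def fit_shim(fieldmap: FieldMap, roi: np.ndarray, order: int = 2) -> ShimSolution:
    """Least-squares shim over ``roi``: fit the basis surface, subtract it.

    The least-squares projection guarantees the shimmed map's ROI RMS never
    exceeds the original; peak-to-peak over the fitted ROI shrinks whenever
    the basis captures part of the field.
    """
    if order not in (1, 2):
        raise ValidationError("shim order must be 1 or 2")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValidationError("shim ROI is empty")
    a, names = _basis_matrix(fieldmap.geometry, roi, order)
    if roi.sum() < a.shape[1]:
        raise ValidationError("ROI smaller than the shim basis")
    f = fieldmap.dfreq_hz[roi]
    coef, *_ = np.linalg.lstsq(a, f, rcond=None)

    yy, xx = fieldmap.geometry.coordinate_grids()
    yc = yy - yy[roi].mean()
    xc = xx - xx[roi].mean()
    full = {"const": np.ones_like(xc), "x": xc, "y": yc,
            "x2-y2": xc**2 - yc**2, "xy": xc * yc}
    surface = sum(c * full[n] for c, n in zip(coef, names))
    shimmed = fieldmap.dfreq_hz - surface

    def stats(values):
        return {
            "peak_to_peak_hz": float(values.max() - values.min()),
            "rms_hz": float(np.sqrt(np.mean(values**2))),
            "std_hz": float(values.std()),
        }

    return ShimSolution(
        coefficients=dict(zip(names, map(float, coef))),
        order=order,
        roi=roi,
        fitted_surface=surface,
        shimmed_map=FieldMap(shimmed, fieldmap.mask, fieldmap.dte_ms, fieldmap.geometry),
        pre_stats=stats(f),
        post_stats=stats(shimmed[roi]),
    )


def _histogram_fwhm(values: np.ndarray, bin_width_hz: float = 10.0) -> float:
    """FWHM of the binned off-resonance histogram, linearly interpolated at
    the half-maximum crossings."""
    lo, hi = values.min(), values.max()
    if hi - lo < bin_width_hz:
        return 0.0
    edges = np.arange(lo, hi + bin_width_hz, bin_width_hz)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    half = counts.max() / 2.0
    above = np.nonzero(counts >= half)[0]
    i0, i1 = above[0], above[-1]
    # interpolate the crossings just outside the half-maximum plateau
    if i0 == 0:
        left = centers[0]
    else:
        c0, c1 = counts[i0 - 1], counts[i0]
        left = centers[i0 - 1] + (half - c0) / (c1 - c0) * bin_width_hz
    if i1 == len(counts) - 1:
        right = centers[-1]
    else:
        c0, c1 = counts[i1], counts[i1 + 1]
        right = centers[i1] + (c0 - half) / (c0 - c1) * bin_width_hz
    return float(right - left)


def field_stats(fieldmap: FieldMap, roi: np.ndarray,
                bin_width_hz: float = 10.0) -> dict[str, float]:
    """Peak-to-peak, histogram FWHM and in-plane gradient statistics over ROI.

    Gradients are finite differences of the field map sampled within the ROI;
    a single-voxel ROI has no defined gradient and is flagged with NaNs.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValidationError("ROI is empty")
    vals = fieldmap.dfreq_hz[roi]
    out = {
        "peak_to_peak_hz": float(vals.max() - vals.min()),
        "fwhm_hz": _histogram_fwhm(vals, bin_width_hz),
        "n_voxels": int(roi.sum()),
    }
    if roi.sum() < 2:
        out["max_gradient_hz_per_mm"] = float("nan")
        out["mean_gradient_hz_per_mm"] = float("nan")
        out["gradient_flag"] = "undefined for single-voxel ROI"
        return out
    dy, dx = fieldmap.geometry.resolution_mm
    gy, gx = np.gradient(fieldmap.dfreq_hz, dy, dx)
    gmag = np.hypot(gy, gx)[roi]
    out["max_gradient_hz_per_mm"] = float(gmag.max())
    out["mean_gradient_hz_per_mm"] = float(gmag.mean())
    return out


def dispersion_per_voxel(gradient_hz_per_mm: float, voxel_extent_mm: float) -> float:
    """Frequency dispersion across one voxel: gradient times voxel extent."""
    if gradient_hz_per_mm < 0 or voxel_extent_mm < 0:
        raise ValidationError("inputs must be non-negative")
    return gradient_hz_per_mm * voxel_extent_mm
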