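"""Digital phantoms: uniform relaxation cylinders and a dynamic short-axis heart.

Three generators cover the study conditions of the acquisition strategies:

* a long-T2* agarose cylinder (150 mm) with an air capillary (dipole field
  perturbation) and a water tube embedded;
* a medium-T2* iron-doped cylinder (80 mm, T2* ~ 20 ms);
* a contracting mid-ventricular short-axis heart with segment-specific T2*,
  cyclic T2* modulation, a smooth background B0 polynomial and a localized
  epicardial field gradient at the inferior/inferolateral border.

All phantoms are voxelized ground-truth parameter maps (``TissueMap``); the
heart phantom additionally records per-frame masks, segment labels and true
per-segment T2* curves for downstream parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .geometry import ImageGeometry, phantom_geometry

__all__ = [
    "TissueMap",
    "HeartPhantomSpec",
    "make_long_t2star_phantom",
    "make_medium_t2star_phantom",
    "make_heart_phantom",
    "perturb_breath_holds",
]


@dataclass
class TissueMap:
    """Voxelized ground-truth parameter fields, optionally time-resolved.

    Arrays are ``(rows, cols)`` for static maps or ``(n_frames, rows, cols)``
    for dynamic ones; frames sample one cardiac cycle at normalized positions
    ``k / n_frames``. ``dfdz_hz_per_mm`` is the through-plane field gradient
    used for intravoxel dephasing.
    """

    s0: np.ndarray
    t2star_ms: np.ndarray
    dfreq_hz: np.ndarray
    fat_fraction: np.ndarray
    geometry: ImageGeometry
    heart_rate_bpm: float | None = None
    dfdz_hz_per_mm: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {self.s0.shape, self.t2star_ms.shape, self.dfreq_hz.shape,
                  self.fat_fraction.shape}
        if len(shapes) != 1:
            raise ValidationError("parameter field shapes differ")
        if self.s0.shape[-2:] != self.geometry.shape:
            raise ValidationError("field shape does not match geometry matrix")
        inside = self.s0 > 0
        if np.any(self.t2star_ms[inside] <= 0):
            raise ValidationError("T2* must be positive inside the object")
        if not np.all(np.isfinite(self.dfreq_hz)):
            raise ValidationError("off-resonance must be finite")
        if np.any(self.fat_fraction < 0) or np.any(self.fat_fraction > 1):
            raise ValidationError("fat fraction must lie in [0, 1]")

    @property
    def is_dynamic(self) -> bool:
        return self.s0.ndim == 3

    @property
    def n_frames(self) -> int:
        return self.s0.shape[0] if self.is_dynamic else 1

    @property
    def cycle_ms(self) -> float:
        if self.heart_rate_bpm is None:
            raise ValidationError("no heart rate attached to this map")
        return 60000.0 / self.heart_rate_bpm

    def object_mask(self) -> np.ndarray:
        return self.s0 > 0

    def frame(self, k: int) -> "TissueMap":
        """Static view of frame ``k`` (identity for static maps)."""
        if not self.is_dynamic:
            return self
        return TissueMap(
            s0=self.s0[k],
            t2star_ms=self.t2star_ms[k],
            dfreq_hz=self.dfreq_hz[k],
            fat_fraction=self.fat_fraction[k],
            geometry=self.geometry,
            heart_rate_bpm=self.heart_rate_bpm,
            dfdz_hz_per_mm=None if self.dfdz_hz_per_mm is None else self.dfdz_hz_per_mm[k],
            meta=self.meta,
        )

    def frame_index_at_time(self, t_ms: float) -> int:
        """Nearest frame to cardiac time ``t_ms`` (wrapped over the cycle)."""
        if not self.is_dynamic:
            return 0
        u = (t_ms % self.cycle_ms) / self.cycle_ms
        return int(np.round(u * self.n_frames)) % self.n_frames


def _disk(geometry: ImageGeometry, center_mm, radius_mm) -> np.ndarray:
    y, x = geometry.coordinate_grids()
    return (y - center_mm[0]) ** 2 + (x - center_mm[1]) ** 2 <= radius_mm**2


def make_long_t2star_phantom(
    geometry: ImageGeometry | None = None,
    base_t2star_ms: float = 30.0,
    diameter_mm: float = 150.0,
    capillary_center_mm: tuple[float, float] = (-30.0, 0.0),
    capillary_diameter_mm: float = 0.5,
    tube_center_mm: tuple[float, float] = (30.0, 0.0),
    tube_diameter_mm: float = 5.0,
    dipole_amplitude_hz_mm2: float = 80.0,
    through_plane_gradient_hz_per_mm: float | None = None,
    s0: float = 1.0,
) -> TissueMap:
    """Uniform agarose cylinder with an air capillary and a water tube.

    The air capillary (S0 = 0) carries a 2D dipole off-resonance perturbation
    ``df = A * cos(2*theta) / r^2`` (A in Hz mm^2), the field of a
    susceptibility cylinder transverse to B0; it falls off as 1/r^2. The
    amplitude default makes T2* shortening visible near the inclusion at
    8 mm slices. ``through_plane_gradient_hz_per_mm`` optionally adds a
    uniform through-plane gradient over the object (slice-thickness sweeps).
    """
    if geometry is None:
        geometry = phantom_geometry()
    if base_t2star_ms <= 0:
        raise ValidationError("base T2* must be positive")
    radius = diameter_mm / 2.0
    if min(geometry.fov_mm) < diameter_mm:
        raise ValidationError("cylinder does not fit in the field of view")
    for name, (cy, cx), d in (
        ("capillary", capillary_center_mm, capillary_diameter_mm),
        ("tube", tube_center_mm, tube_diameter_mm),
    ):
        if np.hypot(cy, cx) + d / 2.0 > radius:
            raise ValidationError(f"{name} lies outside the cylinder")

    y, x = geometry.coordinate_grids()
    obj = _disk(geometry, (0.0, 0.0), radius)
    s0_map = np.where(obj, s0, 0.0)
    t2 = np.where(obj, base_t2star_ms, 1.0)

    # water tube: long-T2* pure water inclusion
    tube = _disk(geometry, tube_center_mm, tube_diameter_mm / 2.0)
    t2[tube & obj] = 60.0

    # air capillary: signal void; sub-voxel, so at least the nearest voxel
    dy, dx = geometry.resolution_mm
    cap = _disk(geometry, capillary_center_mm, capillary_diameter_mm / 2.0)
    if not cap.any():
        i = int(np.argmin(np.abs(y[:, 0] - capillary_center_mm[0])))
        j = int(np.argmin(np.abs(x[0] - capillary_center_mm[1])))
        cap[i, j] = True
    s0_map[cap] = 0.0

    # dipole field around the capillary, zero inside it
    ry = y - capillary_center_mm[0]
    rx = x - capillary_center_mm[1]
    r2 = ry**2 + rx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        cos2t = (rx**2 - ry**2) / r2
        dfreq = dipole_amplitude_hz_mm2 * cos2t / r2
    dfreq[r2 == 0] = 0.0
    dfreq[cap] = 0.0
    dfreq[~obj] = 0.0

    dfdz = None
    if through_plane_gradient_hz_per_mm is not None:
        dfdz = np.where(obj, float(through_plane_gradient_hz_per_mm), 0.0)

    return TissueMap(
        s0=s0_map,
        t2star_ms=t2,
        dfreq_hz=dfreq,
        fat_fraction=np.zeros_like(s0_map),
        geometry=geometry,
        dfdz_hz_per_mm=dfdz,
        meta={
            "kind": "long_t2star",
            "object_radius_mm": radius,
            "capillary_mask": cap,
            "tube_mask": tube & obj,
        },
    )


def make_medium_t2star_phantom(
    geometry: ImageGeometry | None = None,
    t2star_ms: float = 20.0,
    diameter_mm: float = 80.0,
    s0: float = 1.0,
    through_plane_gradient_hz_per_mm: float | None = None,
) -> TissueMap:
    """Uniform iron-doped cylinder, default 80 mm diameter, T2* = 20 ms."""
    if geometry is None:
        geometry = phantom_geometry()
    if t2star_ms <= 0:
        raise ValidationError("T2* must be positive")
    radius = diameter_mm / 2.0
    obj = _disk(geometry, (0.0, 0.0), radius)
    dfdz = None
    if through_plane_gradient_hz_per_mm is not None:
        dfdz = np.where(obj, float(through_plane_gradient_hz_per_mm), 0.0)
    return TissueMap(
        s0=np.where(obj, s0, 0.0),
        t2star_ms=np.where(obj, t2star_ms, 1.0),
        dfreq_hz=np.zeros(geometry.shape),
        fat_fraction=np.zeros(geometry.shape),
        geometry=geometry,
        dfdz_hz_per_mm=dfdz,
        meta={"kind": "medium_t2star", "object_radius_mm": radius},
    )


# Table-derived default segment values (segments 7..12, ms)
_SEG_T2_ED = (16.8, 17.3, 16.3, 12.0, 11.4, 12.5)
_SEG_T2_ES = (13.7, 17.4, 14.8, 10.5, 8.3, 10.9)


@dataclass(frozen=True)
class HeartPhantomSpec:
    """Parameters of the dynamic mid-ventricular short-axis heart phantom.

    Radii are in mm; the end-systolic epicardial radius defaults to the
    area-conserving value (incompressible wall). ``cyclic_amplitude`` is the
    fractional max/min-1 of the per-segment T2* modulation (default 0.27,
    uniform across segments, anchored at the end-systolic values); with
    ``None`` each segment's amplitude is taken from its end-diastolic /
    end-systolic ratio instead. The epicardial gradient sits at
    ``epicardial_gradient_angle_deg`` (display degrees clockwise from
    anterior; 150 deg = inferior/inferolateral border).
    """

    endo_radius_ed_mm: float = 22.0
    epi_radius_ed_mm: float = 30.0
    endo_radius_es_mm: float = 14.0
    epi_radius_es_mm: float | None = None  # None -> conserve wall area
    segment_t2star_ed_ms: tuple[float, ...] = _SEG_T2_ED
    segment_t2star_es_ms: tuple[float, ...] = _SEG_T2_ES
    cyclic_amplitude: float | None = 0.27
    epicardial_gradient_hz_per_mm: float = 20.0
    epicardial_gradient_through_plane_hz_per_mm: float = 20.0
    epicardial_gradient_angle_deg: float = 150.0
    epicardial_gradient_sigma_mm: float = 3.0
    background_coeffs: tuple[float, float, float, float, float] = (
        30.0,   # const (Hz)
        2.0,    # x (Hz/mm)
        -1.5,   # y (Hz/mm)
        0.12,   # x^2 - y^2 (Hz/mm^2)
        0.08,   # xy (Hz/mm^2)
    )
    heart_rate_bpm: float = 60.0
    n_phases: int = 25
    end_systole_fraction: float = 0.36
    t2star_peak_fraction: float = 0.76
    insertion_angle_deg: float = 330.0
    blood_t2star_ms: float = 30.0
    blood_s0: float = 1.0
    myo_s0: float = 1.0
    body_s0: float = 0.7
    body_t2star_ms: float = 30.0
    body_radius_mm: float = 55.0
    epicardial_fat_rim_mm: float = 0.0

    def __post_init__(self):
        if self.n_phases < 2:
            raise ValidationError("heart phantom needs at least 2 cardiac phases")
        if len(self.segment_t2star_ed_ms) != 6 or len(self.segment_t2star_es_ms) != 6:
            raise ValidationError("six segment T2* values required per phase")
        if min(self.segment_t2star_ed_ms) <= 0 or min(self.segment_t2star_es_ms) <= 0:
            raise ValidationError("segment T2* values must be positive")
        if not (0 < self.end_systole_fraction < 1):
            raise ValidationError("end-systole fraction must be in (0, 1)")
        wall_ed = self.epi_radius_ed_mm - self.endo_radius_ed_mm
        if wall_ed <= 0 or self.endo_radius_es_mm <= 0:
            raise ValidationError("radii must give positive wall thickness")
        if self.epi_radius_es_mm is not None:
            wall_es = self.epi_radius_es_mm - self.endo_radius_es_mm
            if wall_es <= wall_ed:
                raise ValidationError(
                    "systolic wall thickness must exceed diastolic wall thickness"
                )

    def epi_radius_es(self) -> float:
        """End-systolic epicardial radius (area-conserving if unspecified)."""
        if self.epi_radius_es_mm is not None:
            return self.epi_radius_es_mm
        ring = self.epi_radius_ed_mm**2 - self.endo_radius_ed_mm**2
        return float(np.sqrt(self.endo_radius_es_mm**2 + ring))


def _contraction(u: np.ndarray, u_sys: float) -> np.ndarray:
    """Smooth periodic 0->1->0 timing curve peaking at ``u_sys``.

    Cosine half-waves on [0, u_sys] (contraction) and [u_sys, 1] (relaxation);
    C1 at the junctions.
    """
    u = np.asarray(u, dtype=float) % 1.0
    out = np.empty_like(u)
    rising = u <= u_sys
    out[rising] = 0.5 * (1 - np.cos(np.pi * u[rising] / u_sys))
    out[~rising] = 0.5 * (1 + np.cos(np.pi * (u[~rising] - u_sys) / (1 - u_sys)))
    return out


def _cyclic_ramp(u: np.ndarray, u_min: float, u_max: float) -> np.ndarray:
    """Smooth periodic curve that is 0 at ``u_min`` and 1 at ``u_max``."""
    u = np.asarray(u, dtype=float) % 1.0
    up = (u - u_min) % 1.0          # position after the minimum
    span = (u_max - u_min) % 1.0    # minimum -> maximum arc length
    out = np.empty_like(u)
    asc = up <= span
    out[asc] = 0.5 * (1 - np.cos(np.pi * up[asc] / span))
    out[~asc] = 0.5 * (1 + np.cos(np.pi * (up[~asc] - span) / (1 - span)))
    return out


def make_heart_phantom(spec: HeartPhantomSpec | None = None,
                       geometry: ImageGeometry | None = None) -> TissueMap:
    """Time-resolved short-axis heart: annulus + blood pool + body tissue.

    Radii interpolate smoothly between end-diastole (frame 0) and end-systole;
    each 60-degree sector carries its segment's T2*, modulated over the cycle
    so the minimum falls at end-systole and the maximum after the onset of
    diastole. The off-resonance field is a smooth background polynomial plus
    a localized gradient at the inferior/inferolateral epicardial border.
    """
    from .segment_analysis import sector_labels  # no cycle: that module is leaf-level

    if spec is None:
        spec = HeartPhantomSpec()
    if geometry is None:
        # compact default grid: 128 x 128 at the in vivo 1.125 mm resolution
        geometry = ImageGeometry(matrix=(128, 128), fov_mm=(144.0, 144.0),
                                 slice_thickness_mm=4.0)

    n = spec.n_phases
    u = np.arange(n) / n
    c = _contraction(u, spec.end_systole_fraction)
    w = _cyclic_ramp(u, spec.end_systole_fraction, spec.t2star_peak_fraction)

    r_endo = spec.endo_radius_ed_mm + (spec.endo_radius_es_mm - spec.endo_radius_ed_mm) * c
    if spec.epi_radius_es_mm is None:
        ring = spec.epi_radius_ed_mm**2 - spec.endo_radius_ed_mm**2
        r_epi = np.sqrt(r_endo**2 + ring)
    else:
        r_epi = spec.epi_radius_ed_mm + (spec.epi_radius_es_mm - spec.epi_radius_ed_mm) * c

    es = np.asarray(spec.segment_t2star_es_ms, dtype=float)
    ed = np.asarray(spec.segment_t2star_ed_ms, dtype=float)
    if spec.cyclic_amplitude is not None:
        amp = np.full(6, float(spec.cyclic_amplitude))
    else:
        amp = np.maximum(ed / es - 1.0, 0.0)
    # (n_frames, 6) true per-segment T2* curves
    seg_t2_frames = es[None, :] * (1.0 + amp[None, :] * w[:, None])

    y, x = geometry.coordinate_grids()
    rr = np.hypot(y, x)
    center = ((geometry.shape[0] - 1) / 2.0, (geometry.shape[1] - 1) / 2.0)

    # static off-resonance: background polynomial + localized epicardial gradient
    c0, cx_, cy_, cxx, cxy = spec.background_coeffs
    dfreq = c0 + cx_ * x + cy_ * y + cxx * (x**2 - y**2) + cxy * x * y
    phi = np.deg2rad(spec.epicardial_gradient_angle_deg)
    # display angle: clockwise from anterior (up); unit vector in (y, x) mm
    nvec = (-np.cos(phi), np.sin(phi))
    gcen = (nvec[0] * (spec.epi_radius_ed_mm + 1.0), nvec[1] * (spec.epi_radius_ed_mm + 1.0))
    gy = y - gcen[0]
    gx = x - gcen[1]
    env = np.exp(-(gy**2 + gx**2) / (2.0 * spec.epicardial_gradient_sigma_mm**2))
    dfreq = dfreq + spec.epicardial_gradient_hz_per_mm * env * (gy * nvec[0] + gx * nvec[1])
    dfdz_static = spec.epicardial_gradient_through_plane_hz_per_mm * env

    shape = (n,) + geometry.shape
    s0 = np.zeros(shape)
    t2 = np.ones(shape)
    ff = np.zeros(shape)
    myo_masks = np.zeros(shape, dtype=bool)
    blood_masks = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int16)
    body = rr <= spec.body_radius_mm

    for k in range(n):
        blood = rr <= r_endo[k]
        myo = (rr > r_endo[k]) & (rr <= r_epi[k])
        s0k = np.where(body, spec.body_s0, 0.0)
        t2k = np.where(body, spec.body_t2star_ms, 1.0)
        s0k[blood] = spec.blood_s0
        t2k[blood] = spec.blood_t2star_ms
        s0k[myo] = spec.myo_s0
        lab = sector_labels(myo, center, spec.insertion_angle_deg, geometry)
        for s in range(6):
            t2k[lab == 7 + s] = seg_t2_frames[k, s]
        if spec.epicardial_fat_rim_mm > 0:
            rim = (rr > r_epi[k]) & (rr <= r_epi[k] + spec.epicardial_fat_rim_mm) & body
            ff[k][rim] = 0.8
        s0[k] = s0k
        t2[k] = t2k
        myo_masks[k] = myo
        blood_masks[k] = blood
        labels[k] = lab

    ed_frame = 0
    es_frame = int(np.argmin(np.pi * r_endo**2))  # minimal cavity area

    return TissueMap(
        s0=s0,
        t2star_ms=t2,
        dfreq_hz=np.broadcast_to(dfreq, shape).copy(),
        fat_fraction=ff,
        geometry=geometry,
        heart_rate_bpm=spec.heart_rate_bpm,
        dfdz_hz_per_mm=np.broadcast_to(dfdz_static, shape).copy(),
        meta={
            "kind": "heart",
            "spec": spec,
            "center": center,
            "phase_fractions": u,
            "endo_radius_mm": r_endo,
            "epi_radius_mm": r_epi,
            "myocardium_masks": myo_masks,
            "blood_masks": blood_masks,
            "segment_labels": labels,
            "segment_t2star_by_frame": seg_t2_frames,
            "modulation_amplitude": amp,
            "ed_frame": ed_frame,
            "es_frame": es_frame,
            "cavity_area_mm2": np.pi * r_endo**2,
        },
    )


def perturb_breath_holds(
    tissue: TissueMap,
    n_holds: int,
    max_shift_vox: float = 2.0,
    max_shear: float = 0.05,
    seed=None,
):
    """Breath-hold copies of a phantom, each under a random shift + shear.

    Returns ``(maps, transforms)``: the transforms (recorded ground truth,
    one per hold) map reference voxel coordinates to the hold's coordinates.
    Magnitudes of 0 yield identical copies; the draw is reproducible for a
    fixed seed.
    """
    from .registration import AffineTransform2D, apply_transform

    if n_holds < 1:
        raise ValidationError("need at least one breath-hold")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maps, transforms = [], []
    for _ in range(n_holds):
        shift = rng.uniform(-max_shift_vox, max_shift_vox, size=2)
        shear = rng.uniform(-max_shear, max_shear, size=2)
        linear = np.array([[1.0, shear[0]], [shear[1], 1.0]])
        t = AffineTransform2D(linear=linear, translation=shift)
        transforms.append(t)
        if np.allclose(linear, np.eye(2)) and np.allclose(shift, 0):
            maps.append(tissue)
            continue
        maps.append(_transform_tissue(tissue, t, apply_transform))
    return maps, transforms


def _transform_tissue(tissue: TissueMap, t, apply_transform) -> TissueMap:
    def warp(a, order=1):
        if a is None:
            return None
        if a.ndim == 3:
            return np.stack([apply_transform(f, t, order=order) for f in a])
        return apply_transform(a, t, order=order)

    s0 = warp(tissue.s0)
    t2 = warp(tissue.t2star_ms)
    t2 = np.where(s0 > 0, np.maximum(t2, 0.01), t2)  # keep T2* positive in-object
    return TissueMap(
        s0=s0,
        t2star_ms=np.maximum(t2, 1e-3),
        dfreq_hz=warp(tissue.dfreq_hz),
        fat_fraction=np.clip(warp(tissue.fat_fraction), 0.0, 1.0),
        geometry=tissue.geometry,
        heart_rate_bpm=tissue.heart_rate_bpm,
        dfdz_hz_per_mm=warp(tissue.dfdz_hz_per_mm),
        meta={**tissue.meta, "breath_hold_transform": t},
    )
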