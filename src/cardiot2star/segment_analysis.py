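"""Mid-ventricular segmental analysis of T2* maps.

The myocardial ring of a mid-ventricular short-axis slice is divided into
the six standard 60-degree sectors (segments 7-12: anterior, anteroseptal,
inferoseptal, inferior, inferolateral, anterolateral), measured from the
anterior right-ventricular insertion. Angles are "display degrees":
clockwise from anterior (image top), so inferior sits at 180 degrees.
Sectors are re-derived per cardiac phase from that phase's myocardial mask
(eroded to compact myocardium) so contraction is tracked and blood or
trabecular voxels stay excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ValidationError
from .geometry import ImageGeometry
from .t2star_fit import T2StarMap

__all__ = [
    "SegmentLabels",
    "SegmentReport",
    "sector_labels",
    "aha_segments",
    "track_roi",
    "segment_stats",
    "paired_comparison",
]

SEGMENT_IDS = (7, 8, 9, 10, 11, 12)
SEGMENT_NAMES = {
    7: "anterior", 8: "anteroseptal", 9: "inferoseptal",
    10: "inferior", 11: "inferolateral", 12: "anterolateral",
}


def display_angle_deg(rows: np.ndarray, cols: np.ndarray, center) -> np.ndarray:
    """Angle in degrees clockwise from anterior (image top), in [0, 360)."""
    dy = rows - center[0]
    dx = cols - center[1]
    return np.degrees(np.arctan2(dx, -dy)) % 360.0


def sector_labels(mask: np.ndarray, center, insertion_angle_deg: float,
                  geometry: ImageGeometry | None = None) -> np.ndarray:
    """Label the six 60-degree sectors of a myocardial mask, 7..12.

    ``insertion_angle_deg`` is the anterior RV insertion (the segment 7/8
    boundary) in display degrees; counting counterclockwise from it yields
    segments 8, 9, 10, 11, 12, 7. Background voxels are 0.
    """
    mask = np.asarray(mask, dtype=bool)
    rr, cc = np.indices(mask.shape)
    phi = display_angle_deg(rr, cc, center)
    delta = (insertion_angle_deg - phi) % 360.0
    k = np.floor(delta / 60.0).astype(int) % 6
    labels = np.where(mask, 7 + (k + 1) % 6, 0).astype(np.int16)
    return labels


@dataclass
class SegmentLabels:
    """Per-voxel segment labels for the mid-ventricular ring, per phase."""

    labels: np.ndarray  # (rows, cols) or (n_phases, rows, cols)
    center: tuple[float, float]
    insertion_angle_deg: float
    flags: list[str] = field(default_factory=list)

    @property
    def per_phase(self) -> bool:
        return self.labels.ndim == 3

    def phase(self, p: int) -> np.ndarray:
        return self.labels[p] if self.per_phase else self.labels


def aha_segments(mask: np.ndarray, center=None,
                 insertion_angle_deg: float = 330.0) -> SegmentLabels:
    """Standard six-sector segmentation of an annulus-like myocardial mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("myocardial mask is empty")
    if center is None:
        rr, cc = np.nonzero(mask)
        center = (float(rr.mean()), float(cc.mean()))
    labels = sector_labels(mask, center, insertion_angle_deg)
    return SegmentLabels(labels=labels, center=center,
                         insertion_angle_deg=insertion_angle_deg)


def track_roi(masks_per_phase: np.ndarray, insertion_angle_deg: float = 330.0,
              erode_iterations: int = 1) -> SegmentLabels:
    """Per-phase sector labels tracking a contracting myocardium.

    Each phase's sectors are re-derived from that phase's mask and centroid;
    masks are eroded (default one voxel) so only compact myocardium enters
    the analysis. Phases with an empty (post-erosion) mask are flagged and
    labeled entirely background.
    """
    masks = np.asarray(masks_per_phase, dtype=bool)
    if masks.ndim != 3:
        raise ValidationError("expected per-phase masks (n_phases, rows, cols)")
    labels = np.zeros(masks.shape, dtype=np.int16)
    flags = []
    center = None
    for p in range(masks.shape[0]):
        m = masks[p]
        if erode_iterations > 0 and m.any():
            m = ndimage.binary_erosion(m, iterations=erode_iterations)
        if not m.any():
            flags.append(f"phase {p}: empty myocardial mask")
            continue
        rr, cc = np.nonzero(masks[p])
        center = (float(rr.mean()), float(cc.mean()))
        labels[p] = sector_labels(m, center, insertion_angle_deg)
    if center is None:
        raise ValidationError("all phases have empty masks")
    return SegmentLabels(labels=labels, center=center,
                         insertion_angle_deg=insertion_angle_deg, flags=flags)


@dataclass
class SegmentReport:
    """Per-(segment, phase) statistics and per-segment cycle summary.

    ``table`` has one row per (segment, cardiac phase) with mean, std and
    voxel count; ``summary`` one row per segment with end-diastolic and
    end-systolic values, cycle max/min, absolute and percent increase
    ``100 * (max - min) / min``.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    ed_phase: int
    es_phase: int

    def segment_curve(self, segment: int) -> np.ndarray:
        rows = self.table[self.table["segment"] == segment].sort_values("phase")
        return rows["mean_t2star_ms"].to_numpy()


def segment_stats(t2maps: list[T2StarMap], labels: SegmentLabels,
                  ed_phase: int = 0, es_phase: int | None = None,
                  min_voxels: int = 10) -> SegmentReport:
    """Per-segment T2* statistics across cardiac phases.

    Means use only voxels with a valid fit; segments below ``min_voxels``
    are flagged (NaN mean, kept in the table). ``es_phase`` defaults to the
    phase with the smallest total labeled area (peak contraction) when not
    given.
    """
    n_phases = len(t2maps)
    if n_phases == 0:
        raise ValidationError("no T2* maps given")
    rows = []
    areas = []
    for p, t2map in enumerate(t2maps):
        lab = labels.phase(p if labels.per_phase else 0)
        if lab.shape != t2map.t2star_ms.shape:
            raise ValidationError("labels and maps must share geometry")
        valid = t2map.valid_mask() & np.isfinite(t2map.t2star_ms)
        areas.append(int((lab > 0).sum()))
        for s in SEGMENT_IDS:
            sel = (lab == s) & valid
            n = int(sel.sum())
            if n >= min_voxels:
                vals = t2map.t2star_ms[sel]
                rows.append((s, p, float(vals.mean()), float(vals.std()), n, ""))
            else:
                rows.append((s, p, np.nan, np.nan, n, "below minimum voxel count"))
    table = pd.DataFrame(rows, columns=["segment", "phase", "mean_t2star_ms",
                                        "std_t2star_ms", "n_voxels", "flag"])
    if es_phase is None:
        es_phase = int(np.argmin(areas)) if n_phases > 1 else 0

    summary_rows = []
    for s in SEGMENT_IDS:
        curve = table[table["segment"] == s].sort_values("phase")["mean_t2star_ms"].to_numpy()
        finite = np.isfinite(curve)
        if not finite.any():
            summary_rows.append((s, SEGMENT_NAMES[s], *[np.nan] * 6))
            continue
        cmax, cmin = np.nanmax(curve), np.nanmin(curve)
        pct = 100.0 * (cmax - cmin) / cmin if cmin > 0 else np.nan
        summary_rows.append((s, SEGMENT_NAMES[s], curve[ed_phase], curve[es_phase],
                             cmax, cmin, cmax - cmin, pct))
    summary = pd.DataFrame(summary_rows, columns=[
        "segment", "name", "end_diastole_ms", "end_systole_ms",
        "cycle_max_ms", "cycle_min_ms", "delta_ms", "percent_increase",
    ])
    return SegmentReport(table=table, summary=summary,
                         ed_phase=ed_phase, es_phase=es_phase)


def paired_comparison(end_diastolic, end_systolic) -> dict[str, float]:
    """Two-sided paired t-test from its closed form.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d`` the per-segment differences
    and ``n - 1`` degrees of freedom; the p-value comes from the t
    distribution CDF. Zero variance of the differences is degenerate and
    flagged (t = 0, p = 1 for identical vectors).
    """
    a = np.asarray(end_diastolic, dtype=float)
    b = np.asarray(end_systolic, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValidationError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return {"t": 0.0 if d.mean() == 0 else np.inf, "p": 1.0 if d.mean() == 0 else 0.0,
                "df": n - 1, "degenerate": True}
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return {"t": float(t), "p": float(p), "df": n - 1, "degenerate": False}
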