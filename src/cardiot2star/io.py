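"""File I/O: NIfTI-1 image series with CSV sidecars, reports, field maps.

An echo image series is stored as a pair of NIfTI volumes (magnitude and
phase, stems ``<stem>_mag.nii.gz`` / ``<stem>_phase.nii.gz``) whose fourth
axis enumerates frames, plus a sidecar table ``<stem>_frames.csv`` listing
(hold, phase, echo, TE, trigger delay) per frame. Phase is stored in
radians in [-pi, pi); magnitude is non-negative.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import EchoImageSeries
from .errors import ConsistencyError, FormatError, ValidationError
from .field_tools import FieldMap
from .geometry import ImageGeometry
from .segment_analysis import SegmentReport
from .t2star_fit import T2StarMap

__all__ = [
    "write_image_series",
    "read_image_series",
    "write_report",
    "write_t2star_map",
    "write_field_map",
]

_SIDECAR_COLS = ["frame", "hold", "cardiac_phase", "echo", "te_ms", "trigger_delay_ms"]


def _affine(geometry: ImageGeometry) -> np.ndarray:
    dy, dx = geometry.resolution_mm
    aff = np.diag([dy, dx, geometry.slice_thickness_mm, 1.0])
    return aff


def _stem(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in ("_mag.nii.gz", "_phase.nii.gz", "_mag.nii", "_phase.nii",
                   "_frames.csv", ".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)])
    return p


def write_image_series(series: EchoImageSeries, path) -> dict[str, Path]:
    """Write a series as magnitude/phase NIfTI pair plus frame sidecar.

    ``path`` is the stem; returns the written file paths. Geometry metadata
    is carried in the NIfTI affine/zooms and a JSON header extension file.
    """
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    frames = list(series.frames())
    all_phase = series.phase()
    mag = np.stack([np.abs(series.data[h, p, e]) for h, p, e in frames], axis=-1)
    pha = np.stack([all_phase[h, p, e] for h, p, e in frames], axis=-1)
    aff = _affine(series.geometry)
    paths = {
        "magnitude": stem.parent / (stem.name + "_mag.nii.gz"),
        "phase": stem.parent / (stem.name + "_phase.nii.gz"),
        "sidecar": stem.parent / (stem.name + "_frames.csv"),
        "meta": stem.parent / (stem.name + "_series.json"),
    }
    nib.save(nib.Nifti1Image(mag[:, :, None, :], aff), paths["magnitude"])
    nib.save(nib.Nifti1Image(pha[:, :, None, :], aff), paths["phase"])
    rows = [
        (k, h, p, e, float(series.te_ms[e]), float(series.trigger_delays_ms[p]))
        for k, (h, p, e) in enumerate(frames)
    ]
    pd.DataFrame(rows, columns=_SIDECAR_COLS).to_csv(paths["sidecar"], index=False)
    meta = {
        "geometry": series.geometry.to_dict(),
        "strategy": series.strategy,
        "heart_rate_bpm": series.heart_rate_bpm,
        "te_ms": [float(t) for t in series.te_ms],
        "trigger_delays_ms": [float(t) for t in series.trigger_delays_ms],
        "hold_echoes": [list(map(int, e)) for e in series.hold_echoes],
    }
    paths["meta"].write_text(json.dumps(meta, indent=1))
    return paths


def read_image_series(path) -> EchoImageSeries:
    """Read a series written by :func:`write_image_series`.

    A missing sidecar is a format error; a frame count differing from the
    sidecar is a consistency error.
    """
    stem = _stem(path)
    mag_path = stem.parent / (stem.name + "_mag.nii.gz")
    pha_path = stem.parent / (stem.name + "_phase.nii.gz")
    sidecar = stem.parent / (stem.name + "_frames.csv")
    meta_path = stem.parent / (stem.name + "_series.json")
    if not mag_path.exists() or not pha_path.exists():
        raise FormatError(f"missing magnitude/phase volumes for stem {stem}")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar table {sidecar}")
    if not meta_path.exists():
        raise FormatError(f"missing series metadata {meta_path}")
    meta = json.loads(meta_path.read_text())
    table = pd.read_csv(sidecar)
    missing = set(_SIDECAR_COLS) - set(table.columns)
    if missing:
        raise FormatError(f"sidecar lacks columns {sorted(missing)}")

    mag = np.asarray(nib.load(mag_path).get_fdata())
    pha = np.asarray(nib.load(pha_path).get_fdata())
    mag = mag.reshape(mag.shape[0], mag.shape[1], -1)
    pha = pha.reshape(pha.shape[0], pha.shape[1], -1)
    n_frames = mag.shape[-1]
    if len(table) != n_frames or pha.shape[-1] != n_frames:
        raise ConsistencyError(
            f"sidecar lists {len(table)} frames but volumes hold {n_frames}"
        )
    geometry = ImageGeometry.from_dict(meta["geometry"])
    te = np.asarray(meta["te_ms"], dtype=float)
    delays = np.asarray(meta["trigger_delays_ms"], dtype=float)
    hold_echoes = [list(e) for e in meta["hold_echoes"]]
    data = np.zeros((len(hold_echoes), delays.size, te.size) + geometry.shape,
                    dtype=complex)
    seen = set()
    for _, row in table.iterrows():
        h, p, e, k = int(row["hold"]), int(row["cardiac_phase"]), int(row["echo"]), int(row["frame"])
        if not (0 <= h < len(hold_echoes) and 0 <= p < delays.size and 0 <= e < te.size):
            raise ConsistencyError(f"sidecar frame {k} indexes outside the series")
        data[h, p, e] = mag[..., k] * np.exp(1j * pha[..., k])
        seen.add((h, p, e))
    expected = {(h, p, e) for h, echoes in enumerate(hold_echoes)
                for p in range(delays.size) for e in echoes}
    if seen != expected:
        raise ConsistencyError("sidecar frames do not cover the declared series")
    return EchoImageSeries(
        data=data, te_ms=te, trigger_delays_ms=delays, hold_echoes=hold_echoes,
        geometry=geometry, strategy=meta.get("strategy", "MS"),
        heart_rate_bpm=meta.get("heart_rate_bpm", 60.0),
    )


def write_report(report: SegmentReport, path) -> Path:
    """Write a segment report as a delimited table, one row per
    (segment, cardiac phase); NaN means stay flagged rows, never dropped."""
    if report.table.empty:
        raise ValidationError("segment report is empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(path, index=False, float_format="%.6g")
    return path


def write_t2star_map(t2map: T2StarMap, path) -> dict[str, Path]:
    """T2* map (ms) plus companion per-voxel fit-status volume."""
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(t2map.geometry)
    paths = {
        "t2star": stem.parent / (stem.name + "_t2star.nii.gz"),
        "status": stem.parent / (stem.name + "_fitstatus.nii.gz"),
    }
    nib.save(nib.Nifti1Image(t2map.t2star_ms[:, :, None], aff), paths["t2star"])
    nib.save(nib.Nifti1Image(t2map.status[:, :, None].astype(np.int16), aff),
             paths["status"])
    return paths


def write_field_map(fieldmap: FieldMap, path) -> Path:
    """Off-resonance map in Hz as a NIfTI volume."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(fieldmap.dfreq_hz[:, :, None], _affine(fieldmap.geometry)), p)
    return p
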