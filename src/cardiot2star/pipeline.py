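"""End-to-end pipeline: phantom -> acquire -> (register) -> fit -> report.

Every stage is logged with the run seed; any stage failure aborts with a
stage-named error. Outputs are deterministic for a fixed config + seed
(byte-identical report tables).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .acquisition import EchoImageSeries, acquire, protocol_preset
from .config import RunConfig
from .errors import StageError
from .geometry import ImageGeometry
from .phantoms import (HeartPhantomSpec, TissueMap, make_heart_phantom,
                       make_long_t2star_phantom, make_medium_t2star_phantom,
                       perturb_breath_holds)
from .registration import apply_transform, estimate_affine, landmarks_from_transform
from .segment_analysis import segment_stats, track_roi
from .t2star_fit import map_fit, roi_mean_t2star

logger = logging.getLogger("cardiot2star")

__all__ = ["ArtifactBundle", "run_pipeline", "build_phantom", "register_series"]


@dataclass
class ArtifactBundle:
    """Everything a pipeline run produced, plus where it was written."""

    config: RunConfig
    tissue: TissueMap
    series: EchoImageSeries
    t2maps: list
    report: object
    paths: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)


def build_phantom(config: RunConfig) -> TissueMap:
    kind = config.phantom["kind"]
    kwargs = {k: v for k, v in config.phantom.items() if k != "kind"}
    geometry = config.image_geometry()
    if kind == "medium":
        return make_medium_t2star_phantom(geometry=geometry, **kwargs)
    if kind == "long":
        return make_long_t2star_phantom(geometry=geometry, **kwargs)
    spec_kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in kwargs.items()}
    return make_heart_phantom(HeartPhantomSpec(**spec_kwargs), geometry=geometry)


def _landmark_grid(shape: tuple[int, int]) -> np.ndarray:
    """A 3x3 grid of fiducial points over the central half of the image."""
    r, c = shape
    rows = np.linspace(r * 0.25, r * 0.75, 3)
    cols = np.linspace(c * 0.25, c * 0.75, 3)
    return np.array([(ri, ci) for ri in rows for ci in cols])


def register_series(series: EchoImageSeries, transforms, points=None) -> EchoImageSeries:
    """Align a multi-breath-hold series to the reference frame.

    ``transforms`` are the per-hold motions (reference -> hold coordinates),
    here known from the generator; landmarks are derived from them (standing
    in for manually set ones), the affine is re-estimated by least squares
    and its correction applied to each hold's magnitude images.
    """
    if points is None:
        points = _landmark_grid(series.geometry.shape)
    data = series.data.copy()
    for h, t in enumerate(transforms):
        lm = landmarks_from_transform(t, points, hold_index=h)
        est = estimate_affine(lm)  # maps hold -> reference coordinates
        if est.max_displacement(series.geometry.shape) < 1e-9:
            continue
        for p in range(series.n_phases):
            for e in series.hold_echoes[h]:
                mag = np.abs(data[h, p, e])
                data[h, p, e] = apply_transform(mag, est)
    out = EchoImageSeries(
        data=data, te_ms=series.te_ms, trigger_delays_ms=series.trigger_delays_ms,
        hold_echoes=series.hold_echoes, geometry=series.geometry,
        strategy=series.strategy, heart_rate_bpm=series.heart_rate_bpm,
        meta={**series.meta, "registered": True},
    )
    return out


def _cylinder_roi(tissue: TissueMap, diameter_mm: float) -> np.ndarray:
    y, x = tissue.geometry.coordinate_grids()
    return np.hypot(y, x) <= diameter_mm / 2.0


def run_pipeline(config: RunConfig, outdir=None) -> ArtifactBundle:
    """Execute phantom -> acquire -> (register) -> fit -> segment -> report."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    rng = np.random.default_rng(config.seed)

    def stage(name):
        stages.append(name)
        logger.info("stage %s (seed=%d)", name, config.seed)

    try:
        stage("phantom")
        tissue = build_phantom(config)
    except Exception as exc:
        raise StageError("phantom", str(exc)) from exc

    name = config.protocol["name"]
    overrides = {k: v for k, v in config.protocol.items() if k != "name"}
    protocol = protocol_preset(name, **overrides)

    transforms = None
    try:
        stage("acquire")
        tissue_per_hold = None
        if protocol.strategy == "MB_CINE":
            reg_cfg = config.registration
            holds, transforms = perturb_breath_holds(
                tissue, protocol.n_holds,
                max_shift_vox=reg_cfg.get("max_shift_vox", 2.0),
                max_shear=reg_cfg.get("max_shear", 0.05),
                seed=rng,
            )
            tissue_per_hold = holds
        series = acquire(tissue, protocol, noise_sigma=config.noise_sigma,
                         seed=rng, tissue_per_hold=tissue_per_hold)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("acquire", str(exc)) from exc

    try:
        if transforms is not None and config.registration.get("enabled", True):
            stage("register")
            series = register_series(series, transforms)
    except Exception as exc:
        raise StageError("register", str(exc)) from exc

    kind = config.phantom["kind"]
    try:
        stage("fit")
        if kind == "heart":
            masks = tissue.meta["myocardium_masks"]
            fit_mask = masks.any(axis=0)
        else:
            fit_mask = tissue.object_mask()
            if fit_mask.ndim == 3:
                fit_mask = fit_mask.any(axis=0)
        t2maps = map_fit(series, fit_mask)
    except Exception as exc:
        raise StageError("fit", str(exc)) from exc

    paths: dict[str, Path] = {}
    try:
        if kind == "heart":
            stage("segment")
            frame_of_phase = [tissue.frame_index_at_time(t)
                              for t in series.trigger_delays_ms]
            phase_masks = tissue.meta["myocardium_masks"][frame_of_phase]
            spec = tissue.meta["spec"]
            labels = track_roi(phase_masks, spec.insertion_angle_deg)
            ed_phase = int(np.argmin(np.abs(np.asarray(frame_of_phase)
                                            - tissue.meta["ed_frame"])))
            es_phase = int(np.argmin(np.abs(np.asarray(frame_of_phase)
                                            - tissue.meta["es_frame"])))
            report = segment_stats(t2maps, labels, ed_phase=ed_phase, es_phase=es_phase)
            stage("report")
            paths["report"] = cio.write_report(report, outdir / "segment_report.csv")
            report.summary.to_csv(outdir / "segment_summary.csv", index=False,
                                  float_format="%.6g")
            paths["summary"] = outdir / "segment_summary.csv"
        else:
            stage("report")
            roi = _cylinder_roi(tissue, 60.0 if kind == "medium" else 20.0)
            rows = []
            for p, t2map in enumerate(t2maps):
                mean, std, n = roi_mean_t2star(t2map, roi)
                rows.append((p, mean, std, n))
            report = pd.DataFrame(rows, columns=["phase", "mean_t2star_ms",
                                                 "std_t2star_ms", "n_voxels"])
            report.to_csv(outdir / "roi_report.csv", index=False, float_format="%.6g")
            paths["report"] = outdir / "roi_report.csv"
        paths.update(cio.write_image_series(series, outdir / "series"))
        for p, t2map in enumerate(t2maps):
            if p in (0, len(t2maps) - 1) or len(t2maps) <= 2:
                paths.update({f"t2star_phase{p}_{k}": v for k, v in
                              cio.write_t2star_map(t2map, outdir / f"phase{p:02d}").items()})
        manifest = {
            "seed": config.seed,
            "config": config.to_dict(),
            "stages": stages,
            "strategy": protocol.strategy,
            "n_frames": series.n_frames,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        paths["manifest"] = outdir / "manifest.json"
    except StageError:
        raise
    except Exception as exc:
        raise StageError("report", str(exc)) from exc

    return ArtifactBundle(config=config, tissue=tissue, series=series,
                          t2maps=t2maps, report=report, paths=paths, stages=stages)
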