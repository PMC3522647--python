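"""Per-voxel T2* estimation by bounded mono-exponential fitting.

The estimator follows the two-stage scheme used for relaxometry: an ordinary
least-squares line through ``(TE, ln S)`` initializes ``T2* = -1/slope``
(with S0 initialized from the sample at the shortest TE), followed by
bounded nonlinear least squares of ``S(TE) = S0 * exp(-TE/T2*)`` on the
magnitude data. Fitting is magnitude-only and unweighted, voxelwise
independent, with no Rician noise-floor correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.optimize import least_squares

from .errors import ValidationError
from .geometry import ImageGeometry

__all__ = [
    "DecaySamples",
    "FitStatus",
    "T2StarMap",
    "DEFAULT_BOUNDS_MS",
    "loglinear_init",
    "fit_monoexp",
    "map_fit",
    "roi_mean_t2star",
]

DEFAULT_BOUNDS_MS = (0.1, 200.0)


class FitStatus(IntEnum):
    OK = 0
    INIT_ONLY = 1       # nonlinear stage failed/did not improve; init retained
    CLIPPED = 2         # log-linear slope degenerate; clipped to bounds
    FAILED = 3          # not enough usable samples


@dataclass(frozen=True)
class DecaySamples:
    """Magnitude samples with their echo times (ms)."""

    te_ms: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "te_ms", np.asarray(self.te_ms, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.te_ms.size < 2:
            raise ValidationError("need at least two decay samples")
        if self.te_ms.shape != self.signal.shape:
            raise ValidationError("TE and signal lists must match")
        if np.any(np.diff(self.te_ms) <= 0):
            raise ValidationError("echo times must be strictly increasing")


@dataclass
class FitResult:
    s0: float
    t2star_ms: float
    residual: float
    status: FitStatus


def loglinear_init(samples: DecaySamples,
                   bounds_ms: tuple[float, float] = DEFAULT_BOUNDS_MS) -> FitResult:
    """Log-linear initialization: OLS line through ``(TE, ln S)``.

    ``T2* = -1/slope``; S0 is initialized from the sample at the minimum TE
    (the estimator quoted for the study; it underestimates S0 by the factor
    ``exp(-TEmin/T2*)``, which the nonlinear stage corrects). Non-positive
    samples are excluded from the log stage; fewer than 2 remaining is a
    failure. A non-negative slope clips T2* to the upper bound and flags
    the voxel.
    """
    keep = samples.signal > 0
    if keep.sum() < 2:
        return FitResult(0.0, bounds_ms[0], np.inf, FitStatus.FAILED)
    te = samples.te_ms[keep]
    lns = np.log(samples.signal[keep])
    slope, _ = np.polyfit(te, lns, 1)
    status = FitStatus.OK
    if slope >= 0 or not np.isfinite(slope):
        t2 = bounds_ms[1]
        status = FitStatus.CLIPPED
    else:
        t2 = float(np.clip(-1.0 / slope, *bounds_ms))
        if t2 in bounds_ms:
            status = FitStatus.CLIPPED if t2 == bounds_ms[1] else status
    s0 = float(samples.signal[keep][np.argmin(te)])  # S(TEmin) rule
    resid = _residual_norm(samples, s0, t2)
    return FitResult(s0, t2, resid, status)


def _residual_norm(samples: DecaySamples, s0: float, t2: float) -> float:
    r = s0 * np.exp(-samples.te_ms / t2) - samples.signal
    return float(np.linalg.norm(r))


def fit_monoexp(samples: DecaySamples, init: FitResult | None = None,
                bounds_ms: tuple[float, float] = DEFAULT_BOUNDS_MS) -> FitResult:
    """Bounded nonlinear least squares of the mono-exponential decay.

    Uses a trust-region-reflective solver with analytic Jacobian starting
    from the log-linear initialization. All samples (including non-positive
    ones) enter the nonlinear stage. On failure or non-improvement the
    initialization is retained and flagged.
    """
    if init is None:
        init = loglinear_init(samples, bounds_ms)
    if init.status == FitStatus.FAILED:
        return init
    te, y = samples.te_ms, samples.signal

    def fun(p):
        return p[0] * np.exp(-te / p[1]) - y

    def jac(p):
        e = np.exp(-te / p[1])
        return np.column_stack([e, p[0] * e * te / p[1] ** 2])

    x0 = np.array([max(init.s0, 1e-12), np.clip(init.t2star_ms, *bounds_ms)])
    try:
        sol = least_squares(
            fun, x0, jac=jac, method="trf",
            bounds=([1e-12, bounds_ms[0]], [np.inf, bounds_ms[1]]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except Exception:
        return FitResult(init.s0, init.t2star_ms, init.residual, FitStatus.INIT_ONLY)
    resid = float(np.linalg.norm(sol.fun))
    if not sol.success or resid > init.residual + 1e-12:
        return FitResult(init.s0, init.t2star_ms, init.residual, FitStatus.INIT_ONLY)
    return FitResult(float(sol.x[0]), float(sol.x[1]), resid, FitStatus.OK)


def _batched_monoexp(te: np.ndarray, y: np.ndarray, s0: np.ndarray, t2: np.ndarray,
                     bounds_ms: tuple[float, float], n_iter: int = 60):
    """Vectorized bounded Levenberg-Marquardt over many voxels at once.

    Same model, bounds and objective as :func:`fit_monoexp`; used by
    :func:`map_fit` for speed. ``y`` is (V, E); parameter vectors are (V,).
    """
    s0 = s0.copy()
    t2 = np.clip(t2, *bounds_ms)
    lam = np.full(s0.shape, 1e-3)

    def cost(s0v, t2v):
        r = s0v[:, None] * np.exp(-te[None, :] / t2v[:, None]) - y
        return np.sum(r * r, axis=1)

    c = cost(s0, t2)
    for _ in range(n_iter):
        e = np.exp(-te[None, :] / t2[:, None])
        r = s0[:, None] * e - y
        j0 = e
        j1 = s0[:, None] * e * te[None, :] / (t2**2)[:, None]
        a00 = np.sum(j0 * j0, axis=1)
        a01 = np.sum(j0 * j1, axis=1)
        a11 = np.sum(j1 * j1, axis=1)
        g0 = np.sum(j0 * r, axis=1)
        g1 = np.sum(j1 * r, axis=1)
        d00 = a00 * (1 + lam)
        d11 = a11 * (1 + lam)
        det = d00 * d11 - a01 * a01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        ds0 = -(d11 * g0 - a01 * g1) / det
        dt2 = -(-a01 * g0 + d00 * g1) / det
        s0_new = np.maximum(s0 + ds0, 1e-12)
        t2_new = np.clip(t2 + dt2, *bounds_ms)
        c_new = cost(s0_new, t2_new)
        better = c_new < c
        s0 = np.where(better, s0_new, s0)
        t2 = np.where(better, t2_new, t2)
        c = np.where(better, c_new, c)
        lam = np.where(better, lam * 0.5, lam * 4.0)
        lam = np.clip(lam, 1e-9, 1e9)
    return s0, t2, np.sqrt(c)


@dataclass
class T2StarMap:
    """Per-voxel fit results for one cardiac phase."""

    t2star_ms: np.ndarray
    s0: np.ndarray
    status: np.ndarray
    residual: np.ndarray
    geometry: ImageGeometry
    cardiac_phase: int = 0
    mask: np.ndarray | None = None

    def valid_mask(self) -> np.ndarray:
        ok = self.status <= FitStatus.INIT_ONLY
        if self.mask is not None:
            ok &= self.mask
        return ok


def _loglinear_batch(te: np.ndarray, y: np.ndarray,
                     bounds_ms: tuple[float, float]):
    """Vectorized log-linear init over (V, E) samples (masked OLS)."""
    pos = y > 0
    n = pos.sum(axis=1)
    usable = n >= 2
    lny = np.where(pos, np.log(np.where(pos, y, 1.0)), 0.0)
    w = pos.astype(float)
    sw = w.sum(axis=1)
    sw = np.where(sw == 0, 1.0, sw)
    tbar = (w * te[None, :]).sum(axis=1) / sw
    ybar = (w * lny).sum(axis=1) / sw
    stt = (w * (te[None, :] - tbar[:, None]) ** 2).sum(axis=1)
    sty = (w * (te[None, :] - tbar[:, None]) * (lny - ybar[:, None])).sum(axis=1)
    stt = np.where(stt == 0, 1e-300, stt)
    slope = sty / stt
    clipped = slope >= -1.0 / bounds_ms[1]
    t2 = np.where(clipped, bounds_ms[1], -1.0 / np.where(slope < 0, slope, -1.0))
    t2 = np.clip(t2, *bounds_ms)
    # S0 from the earliest positive sample (S(TEmin) rule)
    first = np.argmax(pos, axis=1)
    s_first = y[np.arange(y.shape[0]), first]
    s0 = np.where(usable, s_first, 0.0)
    status = np.where(usable,
                      np.where(clipped, FitStatus.CLIPPED, FitStatus.OK),
                      FitStatus.FAILED)
    return s0, t2, status.astype(np.int8)


def map_fit(series, mask: np.ndarray, bounds_ms: tuple[float, float] = DEFAULT_BOUNDS_MS,
            min_echoes: int = 3) -> list[T2StarMap]:
    """Voxelwise T2* maps of an echo image series, one per cardiac phase.

    Breath-holds are merged first (the caller registers them beforehand);
    fitting runs inside ``mask`` only, via the vectorized bounded solver.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("fit mask is empty")
    merged = series.merged()
    echoes = merged.hold_echoes[0]
    if len(echoes) < min_echoes:
        raise ValidationError(f"need at least {min_echoes} echoes for a stable fit")
    te = merged.te_ms[echoes]
    mags = np.abs(merged.data[0][:, echoes])  # (phases, E, rows, cols)
    out = []
    idx = np.nonzero(mask)
    for p in range(merged.n_phases):
        y = mags[p][:, idx[0], idx[1]].T  # (V, E)
        s0_i, t2_i, status = _loglinear_batch(te, y, bounds_ms)
        fit_ok = status != FitStatus.FAILED
        s0_f, t2_f = s0_i.copy(), t2_i.copy()
        resid = np.full(y.shape[0], np.inf)
        if fit_ok.any():
            s0_b, t2_b, r_b = _batched_monoexp(
                te, y[fit_ok], s0_i[fit_ok], t2_i[fit_ok], bounds_ms)
            s0_f[fit_ok] = s0_b
            t2_f[fit_ok] = t2_b
            resid[fit_ok] = r_b
            status[fit_ok] = np.where(
                np.isclose(t2_b, bounds_ms[1]), FitStatus.CLIPPED, FitStatus.OK)
        t2_map = np.full(mask.shape, np.nan)
        s0_map = np.zeros(mask.shape)
        st_map = np.full(mask.shape, int(FitStatus.FAILED), dtype=np.int8)
        r_map = np.full(mask.shape, np.nan)
        t2_map[idx] = t2_f
        s0_map[idx] = s0_f
        st_map[idx] = status
        r_map[idx] = resid
        out.append(T2StarMap(t2_map, s0_map, st_map, r_map, merged.geometry,
                             cardiac_phase=p, mask=mask))
    return out


def roi_mean_t2star(t2map: T2StarMap, roi: np.ndarray | None = None):
    """Mean/std of valid fitted T2* over an ROI (default: the fit mask)."""
    roi = t2map.valid_mask() if roi is None else (np.asarray(roi, bool) & t2map.valid_mask())
    vals = t2map.t2star_ms[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), float("nan"), 0
    return float(vals.mean()), float(vals.std()), int(vals.size)
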