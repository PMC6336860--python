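"""Normalized shape time series and the rank statistics run on them.

Per-frame circle fits are turned into surface-area/volume/neck series
normalized to the first kept frame, then compared first-window versus
last-window with a Mann-Whitney U test (exact by enumeration for small
samples, tie-corrected normal approximation otherwise) and summarized by
the Spearman correlation between neck angle and center distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import geometry as geo
from .contours import FitResult
from .errors import EmptySeriesError, InsufficientDataError

__all__ = [
    "ShapeTimeSeries",
    "UTestResult",
    "build_series",
    "compare_first_final",
    "mann_whitney_u",
    "theta_d_correlation",
]


@dataclass(frozen=True)
class ShapeTimeSeries:
    """Aligned per-kept-frame series.

    ``S_rel`` and ``V_rel`` are normalized to the first kept frame; both
    relative radii are normalized to the first frame's Sec. 1 radius.
    ``theta`` (degrees) and ``d`` are NaN-masked on frames without a neck,
    as is ``r2_rel``.  ``S``, ``V``, ``d`` carry physical units when a
    calibration was applied, pixel units otherwise.
    """

    t: np.ndarray
    S: np.ndarray
    V: np.ndarray
    S_rel: np.ndarray
    V_rel: np.ndarray
    r1_rel: np.ndarray
    r2_rel: np.ndarray
    theta: np.ndarray
    d: np.ndarray
    has_neck: np.ndarray
    frame_index: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "t": self.t,
                "S_rel": self.S_rel,
                "V_rel": self.V_rel,
                "r1_rel": self.r1_rel,
                "r2_rel": self.r2_rel,
                "theta_deg": self.theta,
                "d": self.d,
            }
        )


@dataclass(frozen=True)
class UTestResult:
    """Two-sample Mann-Whitney result with a verdict at level ``alpha``."""

    U: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    verdict: str  # "distinguishable" | "indistinguishable"
    alpha: float

    def to_dict(self) -> dict:
        return {
            "U": self.U,
            "n1": self.n1,
            "n2": self.n2,
            "p_two_sided": self.p_two_sided,
            "method": self.method,
            "verdict": self.verdict,
            "alpha": self.alpha,
        }


def _relabel_for_continuity(fits: list[FitResult]) -> list[FitResult]:
    """Stabilize Sec. 1 / Sec. 2 labels across frames.

    The first budding frame keeps the size-based labeling (mother =
    larger circle); later frames follow nearest-center continuity so the
    mother keeps its identity even if the bud outgrows it.
    """
    out: list[FitResult] = []
    prev = None  # (sec1 center, sec2 center)
    for fit in fits:
        if fit.pre_budding or fit.shape is None:
            out.append(fit)
            continue
        shape = fit.shape
        if prev is not None:
            p1, p2 = prev
            c1, c2 = shape.sec1.center, shape.sec2.center
            keep_cost = np.linalg.norm(c1 - p1) + np.linalg.norm(c2 - p2)
            swap_cost = np.linalg.norm(c1 - p2) + np.linalg.norm(c2 - p1)
            if swap_cost < keep_cost:
                shape = geo.TwoCircleShape(sec1=shape.sec2, sec2=shape.sec1)
                fit = FitResult(
                    shape=shape,
                    circle=fit.circle,
                    rms_residual=fit.rms_residual,
                    n_repeats=fit.n_repeats,
                    per_repeat_shapes=fit.per_repeat_shapes,
                    pre_budding=fit.pre_budding,
                )
        prev = (shape.sec1.center, shape.sec2.center)
        out.append(fit)
    return out


def build_series(
    fits: list[FitResult | None],
    times: np.ndarray,
    um_per_px: float | None = None,
    keep: np.ndarray | None = None,
) -> ShapeTimeSeries:
    """Assemble per-frame fits into a normalized :class:`ShapeTimeSeries`.

    ``fits[i]`` may be None (failed frame); ``keep`` is an optional QC
    mask.  Frames that are dropped by either mechanism do not appear in
    the output.  Pre-budding single-circle fits contribute to S/V as
    single spheres and are NaN-masked in theta, d and r2_rel.
    """
    times = np.asarray(times, dtype=float)
    if len(fits) != len(times):
        raise ValueError("fits and times must have the same length")
    if keep is None:
        keep = np.ones(len(fits), dtype=bool)
    keep = np.asarray(keep, dtype=bool)

    kept = [(i, f) for i, f in enumerate(fits) if keep[i] and f is not None]
    if not kept:
        raise EmptySeriesError("no frame survived quality control")
    if len(kept) < 2:
        raise InsufficientDataError("need at least 2 kept frames to build a series")

    idx = np.array([i for i, _ in kept])
    relabeled = _relabel_for_continuity([f for _, f in kept])
    scale = 1.0 if um_per_px is None else float(um_per_px)

    n = len(relabeled)
    S = np.empty(n)
    V = np.empty(n)
    r1 = np.empty(n)
    r2 = np.full(n, np.nan)
    theta = np.full(n, np.nan)
    d = np.full(n, np.nan)
    has_neck = np.zeros(n, dtype=bool)

    for j, fit in enumerate(relabeled):
        if fit.pre_budding or fit.shape is None:
            r = fit.circle.r * scale
            S[j] = 4.0 * math.pi * r * r
            V[j] = 4.0 / 3.0 * math.pi * r**3
            r1[j] = r
        else:
            g = fit.shape.geometry(scale=scale)
            S[j] = g.S
            V[j] = g.V
            r1[j] = fit.shape.sec1.r * scale
            r2[j] = fit.shape.sec2.r * scale
            theta[j] = g.theta
            d[j] = fit.shape.d * scale
            has_neck[j] = g.config_class is geo.ConfigurationClass.INTERSECTING

    return ShapeTimeSeries(
        t=times[idx],
        S=S,
        V=V,
        S_rel=S / S[0],
        V_rel=V / V[0],
        r1_rel=r1 / r1[0],
        r2_rel=r2 / r1[0],
        theta=theta,
        d=d,
        has_neck=has_neck,
        frame_index=idx,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _u_statistic(ranks: np.ndarray, n1: int) -> float:
    """U for the first sample from pooled midranks."""
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "auto",
    alpha: float = 0.05,
) -> UTestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The exact two-sided p-value is computed by full enumeration of the
    C(n1+n2, n1) group labelings whenever ``n1 + n2 <= 12`` or
    ``mode="exact"``; otherwise a normal approximation with tie-corrected
    variance and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(f"need n1, n2 >= 2, got {n1} and {n2}")
    if mode not in ("auto", "exact"):
        raise ValueError(f"mode must be 'auto' or 'exact', got {mode!r}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    N = n1 + n2
    u = _u_statistic(ranks, n1)
    mu = n1 * n2 / 2.0

    if mode == "exact" or N <= 12:
        dev = abs(u - mu) - 1e-9
        csum = n1 * (n1 + 1) / 2.0
        count = 0
        total = math.comb(N, n1)
        for combo in itertools.combinations(range(N), n1):
            up = ranks[list(combo)].sum() - csum
            if abs(up - mu) >= dev:
                count += 1
        p = count / total
        method = "exact"
    else:
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_sum = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((N + 1) - tie_sum / (N * (N - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(var)
            p = min(2.0 * sps.norm.sf(z), 1.0)
        method = "normal_approx"

    verdict = "distinguishable" if p < alpha else "indistinguishable"
    return UTestResult(
        U=u, n1=n1, n2=n2, p_two_sided=float(p), method=method, verdict=verdict, alpha=alpha
    )


def compare_first_final(
    series: ShapeTimeSeries,
    metric: str = "S_rel",
    window_frac: float = 0.15,
    alpha: float = 0.05,
    mode: str = "auto",
) -> UTestResult:
    """Mann-Whitney comparison of the first vs last ``window_frac`` of frames."""
    if metric not in ("S_rel", "V_rel"):
        raise ValueError(f"metric must be 'S_rel' or 'V_rel', got {metric!r}")
    vals = getattr(series, metric)
    n = len(vals)
    w = int(math.floor(window_frac * n))
    if w < 3 or 2 * w > n:
        raise InsufficientDataError(
            f"series of {n} kept frames is too short for window_frac={window_frac} "
            f"(each window needs >= 3 frames)"
        )
    return mann_whitney_u(vals[:w], vals[-w:], mode=mode, alpha=alpha)


def theta_d_correlation(series: ShapeTimeSeries) -> float:
    """Spearman rank correlation between neck angle and center distance.

    Uses frames with a valid neck only.  Returns NaN when either series
    is constant (correlation undefined).
    """
    m = series.has_neck & np.isfinite(series.theta) & np.isfinite(series.d)
    if int(m.sum()) < 5:
        raise InsufficientDataError(
            f"need >= 5 frames with a valid neck, got {int(m.sum())}"
        )
    th, dd = series.theta[m], series.d[m]
    if np.ptp(th) == 0 or np.ptp(dd) == 0:
        return float("nan")
    return float(sps.spearmanr(th, dd).statistic)
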