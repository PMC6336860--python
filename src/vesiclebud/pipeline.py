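"""End-to-end analysis: frames -> per-frame fits -> series -> statistics.

This is the library-level implementation behind ``vesiclebud analyze``;
the CLI only handles argument parsing, logging setup and exit codes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contours import (
    DEFAULT_FOCUS_THRESHOLD,
    ExtractionConfig,
    NeckConfig,
    decompose_two_circles,
    extract_contour,
    focus_score,
    frame_qc,
)
from .errors import ConfigError, FitError, InsufficientDataError, SegmentationError
from .series import (
    ShapeTimeSeries,
    build_series,
    compare_first_final,
    theta_d_correlation,
)

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_frames", "write_outputs"]

FITS_COLUMNS = [
    "frame",
    "time_s",
    "cx1",
    "cy1",
    "r1",
    "cx2",
    "cy2",
    "r2",
    "d",
    "rms_residual",
    "focus_score",
    "keep",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved parameters of one analysis run.

    ``um_per_px`` and ``s_per_frame`` are optional calibrations; when
    absent, outputs are in pixel and frame-index units (flagged in the
    stats report).  ``step`` subsamples the input frames (the source
    protocol analyzed every 5th or 10th raw video frame; synthetic movies
    are already subsampled, hence the default of 1).
    """

    um_per_px: float | None = None
    s_per_frame: float | None = None
    step: int = 1
    focus_threshold: float = DEFAULT_FOCUS_THRESHOLD
    n_repeats: int = 5
    window_frac: float = 0.15
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ConfigError("step must be >= 1")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if not (0 < self.window_frac <= 0.5):
            raise ConfigError("window_frac must lie in (0, 0.5]")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.um_per_px is not None and self.um_per_px <= 0:
            raise ConfigError("um_per_px must be positive")
        if self.s_per_frame is not None and self.s_per_frame <= 0:
            raise ConfigError("s_per_frame must be positive")
        if self.focus_threshold < 0:
            raise ConfigError("focus_threshold must be >= 0")


@dataclass(frozen=True)
class AnalysisResult:
    fits: pd.DataFrame
    series: ShapeTimeSeries
    stats: dict
    config: AnalysisConfig


def analyze_frames(
    frames: list[np.ndarray],
    config: AnalysisConfig | None = None,
    extraction: ExtractionConfig | None = None,
    neck: NeckConfig | None = None,
    logger: logging.Logger | None = None,
) -> AnalysisResult:
    """Run the full pipeline on an in-memory frame list.

    Frames on which segmentation or fitting fails are logged and dropped
    (keep=False), mirroring the omit-bad-frames protocol.  Raises
    :class:`EmptySeriesError` / :class:`InsufficientDataError` when too
    few frames survive.
    """
    cfg = config or AnalysisConfig()
    log = logger or logging.getLogger("vesiclebud")
    indices = list(range(0, len(frames), cfg.step))
    s_per_frame = cfg.s_per_frame if cfg.s_per_frame is not None else 1.0

    rows = []
    fits = []
    times = []
    keep_mask = []
    for i in indices:
        frame = frames[i]
        t = i * s_per_frame
        times.append(t)
        row = {c: float("nan") for c in FITS_COLUMNS}
        row["frame"] = i
        row["time_s"] = t
        row["keep"] = False
        fit = None
        try:
            contour = extract_contour(frame, extraction)
        except SegmentationError as exc:
            log.warning("frame %d: segmentation failed (%s); dropped", i, exc)
            rows.append(row)
            fits.append(None)
            keep_mask.append(False)
            continue
        score = focus_score(frame, contour)
        qc = frame_qc(score, cfg.focus_threshold)
        row["focus_score"] = qc.focus_score
        if not qc.keep:
            log.info("frame %d: focus %.4f < %.4f; dropped", i, score, cfg.focus_threshold)
            rows.append(row)
            fits.append(None)
            keep_mask.append(False)
            continue
        try:
            fit = decompose_two_circles(
                contour,
                n_repeats=cfg.n_repeats,
                neck_config=neck,
                seed=cfg.seed * 100003 + i,
            )
        except FitError as exc:
            log.warning("frame %d: fit failed (%s); dropped", i, exc)
            rows.append(row)
            fits.append(None)
            keep_mask.append(False)
            continue
        row["rms_residual"] = fit.rms_residual
        row["keep"] = True
        if fit.pre_budding:
            row["cx1"], row["cy1"], row["r1"] = fit.circle.cx, fit.circle.cy, fit.circle.r
            log.info("frame %d: pre-budding (single circle, r=%.2f px)", i, fit.circle.r)
        else:
            s = fit.shape
            row["cx1"], row["cy1"], row["r1"] = s.sec1.cx, s.sec1.cy, s.sec1.r
            row["cx2"], row["cy2"], row["r2"] = s.sec2.cx, s.sec2.cy, s.sec2.r
            row["d"] = s.d
        rows.append(row)
        fits.append(fit)
        keep_mask.append(True)

    fits_df = pd.DataFrame(rows, columns=FITS_COLUMNS)
    series = build_series(
        fits, np.asarray(times), um_per_px=cfg.um_per_px, keep=np.asarray(keep_mask)
    )

    stats: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "calibrated": cfg.um_per_px is not None and cfg.s_per_frame is not None,
        "length_unit": "um" if cfg.um_per_px is not None else "px",
        "time_unit": "s" if cfg.s_per_frame is not None else "frame",
        "n_frames_analyzed": len(indices),
        "n_frames_kept": len(series),
    }
    # window tests need enough kept frames; a short-but-valid series still
    # yields fits and series outputs, with the verdicts reported as missing
    for key, metric in (("surface_area", "S_rel"), ("volume", "V_rel")):
        try:
            stats[key] = compare_first_final(
                series, metric, window_frac=cfg.window_frac, alpha=cfg.alpha
            ).to_dict()
        except InsufficientDataError as exc:
            log.warning("%s first/final comparison unavailable: %s", key, exc)
            stats[key] = {"verdict": None, "error": str(exc)}
    try:
        rho = theta_d_correlation(series)
        stats["spearman_theta_d"] = None if math.isnan(rho) else rho
    except Exception as exc:  # too few neck frames: report, don't fail
        log.warning("theta-d correlation unavailable: %s", exc)
        stats["spearman_theta_d"] = None
    return AnalysisResult(fits=fits_df, series=series, stats=stats, config=cfg)


def write_outputs(result: AnalysisResult, out_dir: str | Path, plots: bool = True) -> None:
    """Write fits CSV, series CSV, stats JSON, resolved config and plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.fits.to_csv(out / "fits.csv", index=False, float_format="%.10g")
    result.series.to_frame().to_csv(out / "series.csv", index=False, float_format="%.10g")
    (out / "stats.json").write_text(json.dumps(result.stats, indent=2, sort_keys=True))
    (out / "config.json").write_text(
        json.dumps({**asdict(result.config), "version": __version__}, indent=2, sort_keys=True)
    )
    if plots:
        _write_plots(result, out)


def _write_plots(result: AnalysisResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = result.series
    time_label = f"time ({result.stats['time_unit']})"
    len_label = result.stats["length_unit"]

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(s.t, s.S_rel, "o-", color="tab:blue", ms=3, label="relative surface area")
    ax.plot(s.t, s.V_rel, "o-", color="m", ms=3, label="relative volume")
    ax.set_xlabel(time_label)
    ax.set_ylabel("relative value")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "series.png", dpi=150)
    plt.close(fig)

    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax2 = ax1.twinx()
    ax1.plot(s.t, s.theta, "o", color="tab:red", ms=3, label="neck angle")
    ax2.plot(s.t, s.d, "o", color="tab:brown", ms=3, label="center distance")
    ax1.set_xlabel(time_label)
    ax1.set_ylabel("neck angle (deg)", color="tab:red")
    ax2.set_ylabel(f"center distance ({len_label})", color="tab:brown")
    fig.tight_layout()
    fig.savefig(out / "neck.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(s.t, s.r1_rel, "o-", color="tab:blue", ms=3, label="Sec. 1 relative radius")
    ax.plot(s.t, s.r2_rel, "o-", color="m", ms=3, label="Sec. 2 relative radius")
    ax.set_xlabel(time_label)
    ax.set_ylabel("relative radius")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "radii.png", dpi=150)
    plt.close(fig)
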