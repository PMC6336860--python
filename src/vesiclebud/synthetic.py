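"""Ground-truthed budding trajectories and rendered phase-contrast movies.

The trajectory generator solves, at every time point, for the unique
two-sphere shape (mother radius, bud radius, center distance) that
simultaneously satisfies three constraints:

1. union volume follows a configured retention curve (constant by default),
2. union surface area follows a smooth monotone growth ramp,
3. the bud-to-mother radius ratio follows a prescribed monotone path.

Because the family of two-sphere shapes with a fixed radius ratio is a
one-parameter family up to scale, the area/volume pair pins the shape
down to a single 1D root-find on the normalized neck opening.

The renderer draws the union-of-discs silhouette with a dark membrane
ring and a bright outer halo (first-order phase-contrast look), an
attenuated ring on the paler bud, additive Gaussian noise, and optional
defocused frames.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import brentq

from . import geometry as geo
from .contours import FitResult
from .errors import ConfigError, InfeasibleTrajectoryError, RenderError
from .geometry import Circle2D, TwoCircleShape
from .series import ShapeTimeSeries, build_series

__all__ = [
    "RenderConfig",
    "SimConfig",
    "SyntheticMovie",
    "TruthFrame",
    "measured_series_from_truth",
    "render_frame",
    "render_movie",
    "simulate_trajectory",
    "truth_to_frame",
]

_SOLVER_RTOL = 1e-12
_RHO_EPS = 1e-9


@dataclass(frozen=True)
class SimConfig:
    """Trajectory parameters.  Lengths in micrometers, times in seconds.

    Defaults model a mother vesicle of 8 um diameter whose surface area
    grows by 20% over the 600 s following bud onset while its volume is
    retained, with the bud reaching 0.65 of the mother radius.
    """

    duration: float = 900.0
    frame_interval: float = 10.0
    r1_0: float = 4.0
    area_growth_factor: float = 1.2
    volume_factor: float = 1.0
    bud_onset: float = 100.0
    growth_duration: float = 600.0
    rho_max: float = 0.65
    rho_exponent: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.r1_0 <= 0:
            raise ConfigError("r1_0 must be positive")
        if self.area_growth_factor < 1:
            raise ConfigError("area_growth_factor must be >= 1 for growth scenarios")
        if self.volume_factor <= 0:
            raise ConfigError("volume_factor must be positive")
        if self.bud_onset < 0:
            raise ConfigError("bud_onset must be >= 0")
        if self.growth_duration <= 0:
            raise ConfigError("growth_duration must be positive")
        if not (0 < self.rho_max < 1):
            raise ConfigError("rho_max must lie in (0, 1)")
        if self.rho_exponent <= 0:
            raise ConfigError("rho_exponent must be positive")


@dataclass(frozen=True)
class RenderConfig:
    """Appearance parameters of the rendered frames (8-bit grayscale)."""

    shape: tuple[int, int] = (256, 256)
    um_per_px: float = 0.08
    background: float = 0.60           # of full scale
    ring_depth: float = 0.35           # darkness of the membrane ring
    ring_width_px: float = 1.8
    halo_height: float = 0.12          # brightness of the outer halo
    halo_offset_px: float = 5.0
    halo_width_px: float = 1.2
    bud_attenuation: float = 0.5       # fractional ring-depth loss on the bud
    noise_sigma: float = 0.012         # of full scale
    blur_sigma_px: float = 6.0         # applied to defocused frames
    defocus_fraction: float = 0.0
    margin_px: int = 10

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ConfigError("um_per_px must be positive")
        if not (0 <= self.background <= 1 and 0 <= self.ring_depth <= 1):
            raise ConfigError("intensity levels must lie within [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if not (0 <= self.bud_attenuation <= 1):
            raise ConfigError("bud_attenuation must lie in [0, 1]")
        if not (0 <= self.defocus_fraction <= 1):
            raise ConfigError("defocus_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TruthFrame:
    """Exact shape of one frame.  Bud fields are NaN before budding."""

    index: int
    t: float
    r1: float
    r2: float
    d: float
    cx1: float
    cy1: float
    cx2: float
    cy2: float
    S: float
    V: float
    theta: float
    defocused: bool = False

    @property
    def budding(self) -> bool:
        return math.isfinite(self.r2)


@dataclass(frozen=True)
class SyntheticMovie:
    frames: np.ndarray  # (T, H, W) uint8
    truth: pd.DataFrame
    shapes: list[TruthFrame]
    seed: int
    manifest: dict


# ---------------------------------------------------------------------------
# trajectory

def _smoothstep(u: float) -> float:
    u = min(max(u, 0.0), 1.0)
    return u * u * (3.0 - 2.0 * u)


def _growth_fraction(t: float, cfg: SimConfig) -> float:
    if t <= cfg.bud_onset:
        return 0.0
    return _smoothstep((t - cfg.bud_onset) / cfg.growth_duration)


def _unit_shape(rho: float, tau: float) -> float:
    """Center distance of the unit-mother shape at normalized opening tau."""
    return (1.0 - rho) + 2.0 * rho * tau


def _isoperimetric_ratio(rho: float, tau: float) -> float:
    d = _unit_shape(rho, tau)
    A = geo.union_surface_area(1.0, rho, d)
    V = geo.union_volume(1.0, rho, d)
    return A / V ** (2.0 / 3.0)


def _solve_shape(rho: float, A_t: float, V_t: float, t: float) -> tuple[float, float, float]:
    """Find (r1, r2, d) with radius ratio rho, area A_t and volume V_t.

    Works in the scale-free family (mother radius 1): the normalized neck
    opening tau in (0, 1) is the root of the isoperimetric-ratio equation,
    then the absolute scale is set from the volume.
    """
    q_req = A_t / V_t ** (2.0 / 3.0)
    lo, hi = 1e-9, 1.0 - 1e-9
    q_lo = _isoperimetric_ratio(rho, lo)
    q_hi = _isoperimetric_ratio(rho, hi)
    if q_req <= q_lo:
        if q_req < q_lo * (1.0 - 1e-9):
            raise InfeasibleTrajectoryError(
                f"at t={t:g}: requested area below the single-sphere minimum "
                f"for this volume (ratio {q_req:.6g} < {q_lo:.6g})"
            )
        tau = lo
    elif q_req > q_hi:
        raise InfeasibleTrajectoryError(
            f"at t={t:g}: requested area exceeds the separated-spheres maximum "
            f"for radius ratio {rho:.4g} (ratio {q_req:.6g} > {q_hi:.6g}); "
            "increase rho_max or lower area_growth_factor"
        )
    else:
        tau = brentq(
            lambda s: _isoperimetric_ratio(rho, s) - q_req,
            lo,
            hi,
            xtol=1e-15,
            rtol=8.9e-16,
        )
    d_unit = _unit_shape(rho, tau)
    v_unit = geo.union_volume(1.0, rho, d_unit)
    lam = (V_t / v_unit) ** (1.0 / 3.0)
    return lam, lam * rho, lam * d_unit


def simulate_trajectory(config: SimConfig) -> list[TruthFrame]:
    """Exact (r1, r2, d) sequence satisfying the area/volume/ratio constraints.

    Shapes are laid out along the x axis in micrometers with the union's
    bounding interval centered on the origin; the mother sits on the left.
    Before ``bud_onset`` each frame is a single sphere.
    """
    n_frames = int(math.floor(config.duration / config.frame_interval)) + 1
    V0 = 4.0 / 3.0 * math.pi * config.r1_0**3
    frames: list[TruthFrame] = []
    for i in range(n_frames):
        t = i * config.frame_interval
        f = _growth_fraction(t, config)
        V_t = V0 * config.volume_factor ** (t / config.duration)
        # area ramp is relative to the sphere holding the current volume,
        # so the constraints stay feasible when volume is not retained
        # (volume_factor < 1); for retained volume this is exactly
        # A0 -> A0 * area_growth_factor
        r_ref = (3.0 * V_t / (4.0 * math.pi)) ** (1.0 / 3.0)
        A_t = 4.0 * math.pi * r_ref**2 * (1.0 + (config.area_growth_factor - 1.0) * f)
        # The ratio ramp must outpace the area ramp (exponent < 1/2) for
        # the neck angle to decrease monotonically; too fast a ramp makes
        # the center distance dip at emergence.  The default exponent is
        # the slowest that keeps d strictly increasing as well.
        rho = config.rho_max * f**config.rho_exponent
        if rho < _RHO_EPS:
            r = (3.0 * V_t / (4.0 * math.pi)) ** (1.0 / 3.0)
            frames.append(
                TruthFrame(
                    index=i,
                    t=t,
                    r1=r,
                    r2=float("nan"),
                    d=float("nan"),
                    cx1=0.0,
                    cy1=0.0,
                    cx2=float("nan"),
                    cy2=float("nan"),
                    S=4.0 * math.pi * r * r,
                    V=V_t,
                    theta=float("nan"),
                )
            )
            continue
        r1, r2, d = _solve_shape(rho, A_t, V_t, t)
        g = geo.sphere_union_geometry(r1, r2, d)
        cx1 = -(d + r2 - r1) / 2.0  # center the union's x-extent on 0
        frames.append(
            TruthFrame(
                index=i,
                t=t,
                r1=r1,
                r2=r2,
                d=d,
                cx1=cx1,
                cy1=0.0,
                cx2=cx1 + d,
                cy2=0.0,
                S=g.S,
                V=g.V,
                theta=g.theta,
            )
        )
    return frames


def truth_to_frame(frames: list[TruthFrame]) -> pd.DataFrame:
    """Tabulate a truth sequence (lengths in micrometers)."""
    return pd.DataFrame(
        {
            "frame": [f.index for f in frames],
            "t": [f.t for f in frames],
            "cx1": [f.cx1 for f in frames],
            "cy1": [f.cy1 for f in frames],
            "r1": [f.r1 for f in frames],
            "cx2": [f.cx2 for f in frames],
            "cy2": [f.cy2 for f in frames],
            "r2": [f.r2 for f in frames],
            "d": [f.d for f in frames],
            "S": [f.S for f in frames],
            "V": [f.V for f in frames],
            "theta": [f.theta for f in frames],
            "defocused": [f.defocused for f in frames],
        }
    )


# ---------------------------------------------------------------------------
# measurement-noise model (desk-scale statistics without rendering)

def measured_series_from_truth(
    frames: list[TruthFrame],
    rel_sigma: float = 0.01,
    seed: int | None = 0,
) -> ShapeTimeSeries:
    """Emulate fitted measurements by perturbing the true lengths.

    Each of r1, r2 and d receives independent multiplicative Gaussian
    noise of relative width ``rel_sigma`` (d is clamped back into the
    intersecting range), mimicking the per-frame error of the contour
    fitting stage; the perturbed lengths are pushed through the standard
    series builder.
    """
    if rel_sigma < 0:
        raise ConfigError("rel_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    fits: list[FitResult] = []
    times = []
    for fr in frames:
        times.append(fr.t)
        if not fr.budding:
            r = fr.r1 * (1.0 + rel_sigma * rng.standard_normal())
            fits.append(
                FitResult(
                    shape=None,
                    circle=Circle2D(cx=0.0, cy=0.0, r=max(r, 1e-9)),
                    rms_residual=0.0,
                    n_repeats=1,
                    pre_budding=True,
                )
            )
            continue
        r1 = fr.r1 * (1.0 + rel_sigma * rng.standard_normal())
        r2 = fr.r2 * (1.0 + rel_sigma * rng.standard_normal())
        d = fr.d * (1.0 + rel_sigma * rng.standard_normal())
        inner, outer = abs(r1 - r2), r1 + r2
        span = outer - inner
        d = min(max(d, inner + 1e-6 * span), outer - 1e-6 * span)
        shape = TwoCircleShape(
            sec1=Circle2D(cx=0.0, cy=0.0, r=r1),
            sec2=Circle2D(cx=d, cy=0.0, r=r2),
        )
        fits.append(
            FitResult(shape=shape, circle=None, rms_residual=0.0, n_repeats=1)
        )
    return build_series(fits, np.asarray(times), um_per_px=1.0)


# ---------------------------------------------------------------------------
# rendering

def render_frame(
    frame: TruthFrame,
    rc: RenderConfig,
    rng: np.random.Generator | None = None,
    defocused: bool | None = None,
) -> np.ndarray:
    """Render one truth shape to an 8-bit grayscale image.

    The membrane ring is a Gaussian intensity valley centered exactly on
    the union boundary (signed distance zero), so the ridge of the dark
    ring marks the true circle.  The bud's ring is attenuated by
    ``bud_attenuation``; the halo is a Gaussian bump offset outwards.
    """
    H, W = rc.shape
    scale = 1.0 / rc.um_per_px
    cx1 = W / 2.0 + frame.cx1 * scale
    cy1 = H / 2.0 + frame.cy1 * scale
    r1 = frame.r1 * scale

    extents = [cx1 - r1, cx1 + r1, cy1 - r1, cy1 + r1]
    if frame.budding:
        cx2 = W / 2.0 + frame.cx2 * scale
        cy2 = H / 2.0 + frame.cy2 * scale
        r2 = frame.r2 * scale
        extents += [cx2 - r2, cx2 + r2, cy2 - r2, cy2 + r2]
    m = rc.margin_px
    if min(extents[0::2]) < m or max(extents[1::2]) > W - m:
        raise RenderError(f"shape exceeds horizontal frame bounds with margin {m} px")
    if min(extents[2::2]) < m or max(extents[3::2]) > H - m:
        raise RenderError(f"shape exceeds vertical frame bounds with margin {m} px")

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    d1 = np.hypot(xx - cx1, yy - cy1) - r1
    if frame.budding:
        d2 = np.hypot(xx - cx2, yy - cy2) - r2
        sdf = np.minimum(d1, d2)
        # the bud's whole contrast (ring and halo) is paler than the mother's
        atten = np.where(d2 < d1, 1.0 - rc.bud_attenuation, 1.0)
    else:
        sdf = d1
        atten = 1.0

    img = (
        rc.background
        - rc.ring_depth * atten * np.exp(-0.5 * (sdf / rc.ring_width_px) ** 2)
        + rc.halo_height * atten * np.exp(-0.5 * ((sdf - rc.halo_offset_px) / rc.halo_width_px) ** 2)
    )
    if defocused is None:
        defocused = frame.defocused
    if defocused and rc.blur_sigma_px > 0:
        img = ndi.gaussian_filter(img, rc.blur_sigma_px)
    if rng is not None and rc.noise_sigma > 0:
        img = img + rng.normal(0.0, rc.noise_sigma, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def render_movie(
    config: SimConfig,
    rc: RenderConfig | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticMovie:
    """Render a full movie with truth table and reproducibility manifest.

    With ``out_dir`` set, writes ``movie.tif`` (multi-page, 8-bit),
    ``truth.csv`` and ``manifest.json``.  Identical config and seed give
    byte-identical outputs.
    """
    rc = rc or RenderConfig()
    truth_frames = simulate_trajectory(config)
    rng = np.random.default_rng(config.seed)
    defocused = rng.random(len(truth_frames)) < rc.defocus_fraction
    truth_frames = [
        TruthFrame(**{**asdict(f), "defocused": bool(defocused[i])})
        for i, f in enumerate(truth_frames)
    ]
    stack = np.stack(
        [render_frame(f, rc, rng=rng) for f in truth_frames], axis=0
    )
    truth = truth_to_frame(truth_frames)
    from . import __version__

    manifest = {
        "seed": config.seed,
        "sim": asdict(config),
        "render": {**asdict(rc), "shape": list(rc.shape)},
        "n_frames": len(truth_frames),
        "version": __version__,
    }
    movie = SyntheticMovie(
        frames=stack, truth=truth, shapes=truth_frames, seed=config.seed, manifest=manifest
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import tifffile

        try:
            tifffile.imwrite(out / "movie.tif", stack, photometric="minisblack")
            truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        except OSError as exc:
            raise OSError(f"failed writing movie artifacts under {out}: {exc}") from exc
    return movie
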