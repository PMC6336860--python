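"""Exact geometry of two overlapping circles revolved into spheres.

A budding vesicle cross-section is modelled as the union of two discs.
Rotating the pair about the axis through both centers produces two
intersecting spheres; every quantity here (exposed surface area, union
volume, neck radius, neck angle) follows from the spherical-cap
decomposition of that solid of revolution.

All functions are pure and unit-agnostic: lengths in, lengths (or their
squares/cubes) out.  Angles are returned in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DegenerateConfigurationError, GeometryDomainError

__all__ = [
    "BOUNDARY_RTOL",
    "Circle2D",
    "ConfigurationClass",
    "SphereUnionGeometry",
    "TwoCircleShape",
    "classify_configuration",
    "monte_carlo_union_volume",
    "neck_angle",
    "neck_plane_offsets",
    "neck_radius",
    "sphere_union_geometry",
    "union_surface_area",
    "union_volume",
]

#: Relative tolerance used to snap ``d`` onto the tangency boundaries.
BOUNDARY_RTOL = 1e-9


class ConfigurationClass(str, Enum):
    """Mutual arrangement of two circles (equivalently, two spheres)."""

    CONTAINED = "contained"
    INTERNALLY_TANGENT = "internally_tangent"
    INTERSECTING = "intersecting"
    EXTERNALLY_TANGENT = "externally_tangent"
    DISJOINT = "disjoint"


@dataclass(frozen=True)
class Circle2D:
    """A circle in image coordinates: center ``(cx, cy)`` and radius ``r``."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        for v in (self.cx, self.cy, self.r):
            if not math.isfinite(v):
                raise GeometryDomainError("circle parameters must be finite")
        if self.r <= 0:
            raise GeometryDomainError(f"circle radius must be positive, got {self.r}")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy], dtype=float)


@dataclass(frozen=True)
class TwoCircleShape:
    """Ordered pair of fitted circles: ``sec1`` = mother, ``sec2`` = bud."""

    sec1: Circle2D
    sec2: Circle2D

    @property
    def d(self) -> float:
        """Euclidean distance between the two centers."""
        return math.hypot(self.sec2.cx - self.sec1.cx, self.sec2.cy - self.sec1.cy)

    def geometry(self, scale: float = 1.0) -> "SphereUnionGeometry":
        """Derived 3D quantities, with all lengths multiplied by ``scale``."""
        return sphere_union_geometry(self.sec1.r * scale, self.sec2.r * scale, self.d * scale)


@dataclass(frozen=True)
class SphereUnionGeometry:
    """Derived quantities of the union of two spheres.

    ``a`` is positive only in the intersecting class; ``theta``, ``x1`` and
    ``x2`` are NaN outside it.
    """

    S: float
    V: float
    a: float
    theta: float
    x1: float
    x2: float
    config_class: ConfigurationClass


def _check_radii(r1: float, r2: float) -> None:
    if not (math.isfinite(r1) and math.isfinite(r2)) or r1 <= 0 or r2 <= 0:
        raise GeometryDomainError(f"radii must be positive and finite, got r1={r1}, r2={r2}")


def _check_distance(d: float) -> None:
    if not math.isfinite(d) or d < 0:
        raise GeometryDomainError(f"center distance must be finite and >= 0, got {d}")


def classify_configuration(
    r1: float, r2: float, d: float, rtol: float = BOUNDARY_RTOL
) -> ConfigurationClass:
    """Classify the mutual arrangement of two circles of radii ``r1``, ``r2``.

    Equalities with the tangency boundaries ``|r1 - r2|`` and ``r1 + r2``
    are resolved within a relative tolerance of ``rtol`` (scaled by
    ``r1 + r2``).  Concentric equal circles (``d = 0``, ``r1 = r2``) are
    reported as ``CONTAINED`` — the union is a single sphere.
    """
    _check_radii(r1, r2)
    _check_distance(d)
    inner = abs(r1 - r2)
    outer = r1 + r2
    tol = rtol * outer
    if abs(d - outer) <= tol:
        return ConfigurationClass.EXTERNALLY_TANGENT
    if abs(d - inner) <= tol:
        if inner <= tol:  # concentric equal circles: a single sphere
            return ConfigurationClass.CONTAINED
        return ConfigurationClass.INTERNALLY_TANGENT
    if d > outer:
        return ConfigurationClass.DISJOINT
    if d < inner:
        return ConfigurationClass.CONTAINED
    return ConfigurationClass.INTERSECTING


def _require_intersecting(r1: float, r2: float, d: float, op: str) -> None:
    cls = classify_configuration(r1, r2, d)
    if cls is not ConfigurationClass.INTERSECTING:
        raise GeometryDomainError(
            f"{op} requires an intersecting configuration, got {cls.value} "
            f"(r1={r1}, r2={r2}, d={d})"
        )


def neck_plane_offsets(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Signed distances from each center to the plane of the neck circle.

    ``x1 = (d^2 + r1^2 - r2^2) / (2 d)`` and ``x2 = d - x1``; the plane at
    distance ``x1`` from center 1 (towards center 2) contains the circle in
    which the two sphere surfaces meet.  Either offset may be negative when
    the neck plane lies beyond the respective center.
    """
    if d == 0:
        raise DegenerateConfigurationError("neck plane undefined for coincident centers")
    _require_intersecting(r1, r2, d, "neck_plane_offsets")
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    return x1, d - x1


def neck_radius(r1: float, r2: float, d: float) -> float:
    """Radius of the circle in which the two sphere surfaces intersect."""
    _require_intersecting(r1, r2, d, "neck_radius")
    x1, _ = neck_plane_offsets(r1, r2, d)
    sq = r1 * r1 - x1 * x1
    return math.sqrt(max(sq, 0.0))


def union_surface_area(r1: float, r2: float, d: float) -> float:
    """Exposed surface area of the union of the two spheres.

    For the intersecting class this is the sum of the two exposed
    spherical-cap areas, ``2 pi r1 (r1 + x1) + 2 pi r2 (r2 + x2)``.  A
    contained bud contributes nothing (only the larger sphere's surface is
    exposed); disjoint or externally tangent spheres expose both full
    surfaces.
    """
    cls = classify_configuration(r1, r2, d)
    if cls in (ConfigurationClass.CONTAINED, ConfigurationClass.INTERNALLY_TANGENT):
        r = max(r1, r2)
        return 4.0 * math.pi * r * r
    if cls in (ConfigurationClass.DISJOINT, ConfigurationClass.EXTERNALLY_TANGENT):
        return 4.0 * math.pi * (r1 * r1 + r2 * r2)
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    x2 = d - x1
    return 2.0 * math.pi * (r1 * (r1 + x1) + r2 * (r2 + x2))


def union_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the union of the two spheres.

    Intersecting case: sum of the full sphere volumes minus the lens-shaped
    overlap,

    ``V_lens = pi (r1 + r2 - d)^2 (d^2 + 2 d (r1 + r2) - 3 (r1^2 + r2^2)
    + 6 r1 r2) / (12 d)``.
    """
    cls = classify_configuration(r1, r2, d)
    if cls in (ConfigurationClass.CONTAINED, ConfigurationClass.INTERNALLY_TANGENT):
        r = max(r1, r2)
        return 4.0 / 3.0 * math.pi * r**3
    if cls in (ConfigurationClass.DISJOINT, ConfigurationClass.EXTERNALLY_TANGENT):
        return 4.0 / 3.0 * math.pi * (r1**3 + r2**3)
    lens = (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d * d + 2.0 * d * (r1 + r2) - 3.0 * (r1 * r1 + r2 * r2) + 6.0 * r1 * r2)
        / (12.0 * d)
    )
    return 4.0 / 3.0 * math.pi * (r1**3 + r2**3) - lens


def neck_angle(r1: float, r2: float, d: float) -> float:
    """Angle (degrees) between the two tangent lines at the neck.

    With ``cos(phi) = (r1^2 + r2^2 - d^2) / (2 r1 r2)``, the returned angle
    is ``180 - phi``: it tends to 180 deg as the bud merges back into the
    mother (internal tangency) and to 0 deg as the neck pinches off
    (external tangency), decreasing strictly with ``d`` for fixed radii.
    """
    _require_intersecting(r1, r2, d, "neck_angle")
    cos_phi = (r1 * r1 + r2 * r2 - d * d) / (2.0 * r1 * r2)
    cos_phi = min(1.0, max(-1.0, cos_phi))
    return 180.0 - math.degrees(math.acos(cos_phi))


def sphere_union_geometry(r1: float, r2: float, d: float) -> SphereUnionGeometry:
    """Bundle ``S``, ``V``, neck radius/angle and neck-plane offsets."""
    cls = classify_configuration(r1, r2, d)
    S = union_surface_area(r1, r2, d)
    V = union_volume(r1, r2, d)
    if cls is ConfigurationClass.INTERSECTING:
        x1, x2 = neck_plane_offsets(r1, r2, d)
        a = neck_radius(r1, r2, d)
        theta = neck_angle(r1, r2, d)
    else:
        x1 = x2 = theta = float("nan")
        a = 0.0
    return SphereUnionGeometry(S=S, V=V, a=a, theta=theta, x1=x1, x2=x2, config_class=cls)


def monte_carlo_union_volume(
    r1: float,
    r2: float,
    d: float,
    n_points: int = 1_000_000,
    seed: int | None = None,
    chunk: int = 500_000,
) -> tuple[float, float]:
    """Rejection-sampling estimate of the union volume, with standard error.

    Uniform samples are drawn in the bounding box of the two spheres
    (centers at ``0`` and ``d`` on the x axis); the returned standard error
    is the binomial error of the acceptance fraction scaled by the box
    volume.  Intended as an independent oracle for :func:`union_volume`.
    """
    _check_radii(r1, r2)
    _check_distance(d)
    if n_points < 1:
        raise ValueError("n_points must be positive")
    rng = np.random.default_rng(seed)
    lo = np.array([min(-r1, d - r2), -max(r1, r2), -max(r1, r2)])
    hi = np.array([max(r1, d + r2), max(r1, r2), max(r1, r2)])
    box = float(np.prod(hi - lo))
    hits = 0
    remaining = n_points
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.uniform(lo, hi, size=(m, 3))
        in1 = np.einsum("ij,ij->i", pts, pts) <= r1 * r1
        q = pts.copy()
        q[:, 0] -= d
        in2 = np.einsum("ij,ij->i", q, q) <= r2 * r2
        hits += int(np.count_nonzero(in1 | in2))
        remaining -= m
    p = hits / n_points
    estimate = box * p
    stderr = box * math.sqrt(max(p * (1.0 - p), 1e-300) / n_points)
    return estimate, stderr
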