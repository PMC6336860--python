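"""Shared fixtures: rendered synthetic frames with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from vesiclebud import synthetic as syn


def make_truth_frame(
    r1: float, r2: float | None, d: float | None, index: int = 0, t: float = 0.0
) -> syn.TruthFrame:
    """Truth frame in micrometer coordinates centered on the origin."""
    if r2 is None:
        return syn.TruthFrame(
            index=index, t=t, r1=r1, r2=float("nan"), d=float("nan"),
            cx1=0.0, cy1=0.0, cx2=float("nan"), cy2=float("nan"),
            S=4 * np.pi * r1**2, V=4 / 3 * np.pi * r1**3, theta=float("nan"),
        )
    from vesiclebud import geometry as geo

    g = geo.sphere_union_geometry(r1, r2, d)
    cx1 = -(d + r2 - r1) / 2.0
    return syn.TruthFrame(
        index=index, t=t, r1=r1, r2=r2, d=d,
        cx1=cx1, cy1=0.0, cx2=cx1 + d, cy2=0.0, S=g.S, V=g.V, theta=g.theta,
    )


def render_shape(
    r1: float,
    r2: float | None,
    d: float | None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    shape: tuple[int, int] = (160, 160),
    defocused: bool = False,
    **render_kwargs,
) -> tuple[np.ndarray, syn.TruthFrame, syn.RenderConfig]:
    """Render a single shape at 1 um/px so pixel and truth units coincide."""
    rc = syn.RenderConfig(
        shape=shape, um_per_px=1.0, noise_sigma=noise_sigma, **render_kwargs
    )
    frame = make_truth_frame(r1, r2, d)
    rng = np.random.default_rng(seed) if noise_sigma > 0 else None
    img = syn.render_frame(frame, rc, rng=rng, defocused=defocused)
    return img, frame, rc


@pytest.fixture(scope="session")
def two_disc_frame():
    """Noiseless render of the (r1=30, r2=20, d=35) px reference union."""
    img, frame, rc = render_shape(30.0, 20.0, 35.0)
    return img, frame


@pytest.fixture(scope="session")
def default_trajectory():
    return syn.simulate_trajectory(syn.SimConfig())


@pytest.fixture(scope="session")
def default_movie():
    return syn.render_movie(syn.SimConfig())
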