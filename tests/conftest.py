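"""Shared synthetic-microscopy fixtures.

Expensive renders and tracking runs are session-scoped so module tests and
the acceptance suite reuse them instead of recomputing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flowquant import fixtures as fx
from flowquant import suspension as susp
from flowquant import tracking as trk

CHANNEL_H = 128  # px, suspension-flow channel height
VMAX = 300.0     # µm/s, suspension-flow centerline speed
FLOW_KW = dict(texture_density=0.035, n_frames=30, fps=100.0, um_per_px=1.0,
               frame_shape=(CHANNEL_H, 256), speckle_sigma_px=1.1)
TRACK_KW = dict(max_features=450, window_size_px=7, min_corner_sep_px=4,
                reseed_every=5)


def parabolic_profile(y_um):
    return VMAX * (1.0 - (2.0 * np.asarray(y_um) / CHANNEL_H) ** 2)


def blunted_profile(y_um):
    return VMAX * (1.0 - np.abs(2.0 * np.asarray(y_um) / CHANNEL_H) ** 6)


def plug_profile(y_um):
    return np.full_like(np.asarray(y_um, dtype=float), VMAX)


@pytest.fixture(scope="session")
def moving_cells():
    """10 well-separated cells at 125 µm/s over 50 noise-free frames."""
    stack, truth = fx.render_moving_cells(
        n_cells=10, velocity_um_s=125.0, n_frames=50, fps=25.0, um_per_px=1.0, seed=11
    )
    return stack, truth


@pytest.fixture(scope="session")
def moving_cells_detections(moving_cells):
    stack, _ = moving_cells
    return trk.detect_stack(stack, 7, min_mass=50.0)


@pytest.fixture(scope="session")
def parabolic_flow():
    stack, truth = fx.render_suspension_flow(parabolic_profile, seed=4, **FLOW_KW)
    feats = susp.detect_and_track_flow(stack, **TRACK_KW)
    return stack, truth, feats


@pytest.fixture(scope="session")
def plug_flow():
    kw = dict(FLOW_KW, n_frames=15)
    stack, truth = fx.render_suspension_flow(plug_profile, seed=5, **kw)
    feats = susp.detect_and_track_flow(stack, **TRACK_KW)
    return stack, truth, feats


@pytest.fixture(scope="session")
def blunted_flow():
    stack, truth = fx.render_suspension_flow(blunted_profile, seed=6, **FLOW_KW)
    feats = susp.detect_and_track_flow(stack, **TRACK_KW)
    return stack, truth, feats


def two_population_tables(seed: int = 7, n_per: int = 150):
    """Two samples of cells from slow and fast subpopulations.

    Both velocity and size separate the populations by ten within-cluster
    standard deviations, emulating pooled single-cell feature tables from a
    healthy and a diseased sample with different mixing proportions.
    """
    rng = np.random.default_rng(seed)

    def pop(v_mu, s_mu, n):
        return pd.DataFrame(
            {"velocity_um_s": rng.normal(v_mu, 5.0, n),
             "area_um2": rng.normal(s_mu, 2.0, n)}
        )

    # sample A: 70% slow / 30% fast; sample B: 30% slow / 70% fast
    a = pd.concat([pop(50.0, 20.0, int(0.7 * n_per)), pop(100.0, 40.0, int(0.3 * n_per))],
                  ignore_index=True)
    b = pd.concat([pop(50.0, 20.0, int(0.3 * n_per)), pop(100.0, 40.0, int(0.7 * n_per))],
                  ignore_index=True)
    truth_a = np.array([0] * int(0.7 * n_per) + [1] * int(0.3 * n_per))
    truth_b = np.array([0] * int(0.3 * n_per) + [1] * int(0.7 * n_per))
    return [("sample_a", a), ("sample_b", b)], {"sample_a": truth_a, "sample_b": truth_b}
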