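import numpy as np
import pytest

from monolayer_mech.mechanics import GEOMETRY_PRESETS, MechParams


@pytest.fixture(scope="session")
def wt_geometry():
    return GEOMETRY_PRESETS["wt"]


@pytest.fixture(scope="session")
def wt_params():
    """Wild-type-like shell rheology (median prestress/modulus/fluidity)."""
    return MechParams(T0_mN_per_m=0.35, KA0_mN_per_m=0.02, beta=0.5, t0_s=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def demo_config_stages():
    """Stage list of the bundled end-to-end synthetic demo."""
    return [
        {"stage": "simulate_field", "shape": [64, 64], "xi_um": 30, "sigma": 5,
         "drift": [10, 0], "n_frames": 3},
        {"stage": "velocimetry"},
        {"stage": "simulate_tracks", "n": 50, "n_frames": 60, "model": "brownian",
         "D_um2_per_min": 1.0, "dt_min": 7.5, "box_um": 2000},
        {"stage": "msd", "dt_min": 7.5, "fit_hi_min": 120.0},
        {"stage": "simulate_tessellation", "n_cells": 150, "frame_shape": [256, 256],
         "mean_area_um2": 300, "skew_target": 2.0},
        {"stage": "morphometry"},
        {"stage": "simulate_force_curve", "preset": "wt", "noise_rel": 0.01},
        {"stage": "mech_fit"},
    ]
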