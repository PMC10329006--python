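"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

import meiotrack as mt


@pytest.fixture(scope="session")
def small_geometry():
    """Short acquisition covering the stretch window and early anaphase."""
    return mt.AcquisitionGeometry(n_t=20, t_onset_index=16)


@pytest.fixture(scope="session")
def fate_geometry():
    """Acquisition long enough to call fates at +120 s."""
    return mt.AcquisitionGeometry(n_t=40, t_onset_index=27)


@pytest.fixture(scope="session")
def control_cohort(small_geometry):
    cfg = mt.SyntheticCohortConfig(n_oocytes=5, geometry=small_geometry,
                                   seed=11)
    tracks, truth = mt.simulate_cohort(cfg)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def control_metrics(control_cohort):
    _, tracks, _ = control_cohort
    return mt.compute_metrics(tracks)


@pytest.fixture(scope="session")
def knl1_cohort(fate_geometry):
    cfg = mt.SyntheticCohortConfig(
        n_oocytes=10, preset=mt.PRESETS["knl1_null"],
        geometry=fate_geometry, seed=21)
    tracks, truth = mt.simulate_cohort(cfg)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def rendered_oocyte(small_geometry):
    """One rendered control oocyte with its ground-truth tracks."""
    cfg = mt.SyntheticCohortConfig(n_oocytes=1, geometry=small_geometry,
                                   seed=5)
    tracks, truth = mt.simulate_cohort(cfg)
    odf = tracks[tracks["oocyte_id"] == 1]
    stack, meta = mt.render_stack(odf, small_geometry, snr=8.0, seed=1)
    return odf, stack, meta


def truth_positions(tracks, object_class, time_s):
    """Positions of all objects of a class at one frame (test helper)."""
    sel = tracks[(tracks["object_class"] == object_class)
                 & np.isclose(tracks["time_s"], time_s)]
    return sel[["x_um", "y_um", "z_um"]].to_numpy()
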