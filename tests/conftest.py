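"""Shared fixtures: geometry presets, phantom, cached noise calibrations.

Heavy artifacts (the system matrix, CNR calibrations, the tuned TV weight)
are session-scoped and computed lazily so independent test modules share
one copy.  All randomness is seeded; the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from nldct.acquisition import calibrate_incident_intensity, tune_tv_lambda
from nldct.phantom import build_phantom, cnr_rois, default_rois
from nldct.projection import FanBeamGeometry, desk_geometry

#: master seed for every stochastic fixture in the suite
SEED = 7


@pytest.fixture(scope="session")
def desk_geom() -> FanBeamGeometry:
    return desk_geometry()


@pytest.fixture(scope="session")
def toy_geom() -> FanBeamGeometry:
    """A small fan-beam system (32x32 image) for solver-convergence tests."""
    return FanBeamGeometry(
        n_detectors=48,
        detector_spacing_iso=2.0,
        n_angles=60,
        source_to_detector=600.0,
        source_to_isocenter=400.0,
        image_rows=32,
        image_cols=32,
        pixel_size=2.0,
    )


@pytest.fixture(scope="session")
def phantom128():
    return build_phantom(128)


@pytest.fixture(scope="session")
def rois128() -> dict:
    return {r.role: r for r in default_rois(128)}


@pytest.fixture(scope="session")
def calibrated_i0(desk_geom, phantom128):
    """Lazily calibrated incident intensity per CNR target (cached)."""
    liver, muscle = cnr_rois(128)
    cache: dict[float, float] = {}

    def get(cnr_target: float) -> float:
        if cnr_target not in cache:
            cache[cnr_target] = calibrate_incident_intensity(
                phantom128, desk_geom, cnr_target, liver, muscle, SEED
            )
        return cache[cnr_target]

    return get


@pytest.fixture(scope="session")
def tuned_tv_lambda(desk_geom, phantom128, calibrated_i0):
    """Lazily tuned TV-L1 weight per CNR target (cached)."""
    _, muscle = cnr_rois(128)
    cache: dict[float, float] = {}

    def get(cnr_target: float) -> float:
        if cnr_target not in cache:
            cache[cnr_target] = tune_tv_lambda(
                phantom128, desk_geom, calibrated_i0(cnr_target), muscle, SEED
            )
        return cache[cnr_target]

    return get
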