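import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import minipvdr as m

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


#: reduced scoring region used throughout the tests: same lateral extent and
#: voxel sizes as the full study grid, shallower z (covers the 70 MeV range)
SMALL_GEOMETRY = m.GeometrySpec(air_gap=5.0, scoring_dims=(6.0, 6.0, 6.0),
                                dose_voxel=(0.5, 0.5, 1.0),
                                let_voxel=(1.0, 1.0, 10.0))

QUIET_PARAMS = m.GeneratorParams(noise_rel_dose=0.0, noise_rel_let=0.0)


@pytest.fixture(scope="session")
def ref_collimator():
    """Reference collimator: 2 mm holes at 6 mm c-t-c."""
    return m.CollimatorSpec(hole_diameter=2.0, ctc=6.0)


@pytest.fixture(scope="session")
def ref_phantom(ref_collimator):
    """Reference 70 MeV phantom with default statistical noise."""
    return m.generate_phantom(m.default_beam(70.0), ref_collimator,
                              SMALL_GEOMETRY, m.GeneratorParams(),
                              prescription=2.0, seed=1)


@pytest.fixture(scope="session")
def quiet_phantom(ref_collimator):
    """Reference phantom without statistical noise."""
    return m.generate_phantom(m.default_beam(70.0), ref_collimator,
                              SMALL_GEOMETRY, QUIET_PARAMS,
                              prescription=2.0, seed=1)


@pytest.fixture(scope="session")
def gap_records(ref_collimator):
    """PVDR records at 1 cm depth for air gaps 5/10/15 cm (noise-free)."""
    out = {}
    for gap in (5.0, 10.0, 15.0):
        geom = m.GeometrySpec(air_gap=gap, scoring_dims=(6.0, 6.0, 3.0),
                              dose_voxel=(0.5, 0.5, 1.0),
                              let_voxel=(1.0, 1.0, 10.0))
        ds = m.generate_phantom(m.default_beam(70.0), ref_collimator, geom,
                                QUIET_PARAMS, prescription=2.0, seed=1)
        out[gap] = m.analyze_dataset(
            ds, m.TissueModelSpec("mcnamara", 3.0), depths=(1.0,))[0]
    return out


@pytest.fixture(scope="session")
def sweep_df():
    """Small Cartesian sweep: 2 hole sizes x 3 models x 2 alpha/beta."""
    cfg = m.SweepConfig(
        energies=(70.0,), hole_diameters=(1.0, 2.0), ctc_factors=(3.0,),
        air_gaps=(5.0,), depths={70.0: (1.0, 2.0, 4.0)},
        models=("mcnamara", "carabe", "wedenberg"), alpha_betas=(3.0, 10.0),
        prescriptions=(2.0,), geometry=SMALL_GEOMETRY,
        params=m.GeneratorParams(), seed=7)
    return m.run_parameter_sweep(cfg)
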