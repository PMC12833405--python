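import pytest

import ukawear as uw


@pytest.fixture(scope="session")
def implant_spec():
    return uw.ImplantSpec()


@pytest.fixture(scope="session")
def pe_foundation():
    return uw.FoundationParams(youngs_modulus=940.0, poisson_ratio=0.46,
                               layer_thickness=8.0, friction_coefficient=0.04)


@pytest.fixture(scope="session")
def cartilage_foundation():
    return uw.FoundationParams(youngs_modulus=15.0, poisson_ratio=0.475,
                               layer_thickness=6.0, friction_coefficient=0.04)


@pytest.fixture()
def medial_geometry(implant_spec):
    return uw.make_medial_compartment(implant_spec, resolution=1.0)


@pytest.fixture()
def lateral_geometry():
    return uw.make_lateral_cartilage_surface(uw.LateralConfig(), resolution=1.0)


# -- full simulation runs shared by the trend and acceptance tests ----------

@pytest.fixture(scope="session")
def uka_result():
    return uw.run(uw.SimulationConfig(scenario="UKA"))


@pytest.fixture(scope="session")
def ukak_result():
    return uw.run(uw.SimulationConfig(scenario="UKAK"))


@pytest.fixture(scope="session")
def ukak_halfstep_result():
    return uw.run(uw.SimulationConfig(
        scenario="UKAK",
        archard=uw.ArchardParams(cycles_per_step=2.5e5, n_steps=20)))
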