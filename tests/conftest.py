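import numpy as np
import pytest

from spionlab.constants import CONSTANTS
from spionlab.magnetodynamics import (
    FieldExcitation,
    MediumSpec,
    ParticleSpec,
    SuspensionSpec,
)


@pytest.fixture
def medium_310k() -> MediumSpec:
    """Water-like carrier at body temperature (the reference model medium)."""
    return MediumSpec(viscosity=8.9e-4, temperature=310.0)


@pytest.fixture
def particle_16nm() -> ParticleSpec:
    return ParticleSpec(
        core_diameter=16e-9,
        hydrodynamic_ratio=1.5,
        anisotropy_constant=21e3,
        core_saturation_magnetization=300e3,
    )


@pytest.fixture
def suspension(particle_16nm, medium_310k) -> SuspensionSpec:
    return SuspensionSpec(
        particle=particle_16nm, medium=medium_310k, number_density=1e20
    )


@pytest.fixture
def excitation_58khz() -> FieldExcitation:
    """58.3 kHz / 20 mT reference excitation."""
    return FieldExcitation(frequency=58.3e3, induction=20e-3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_suspension(rng: np.random.Generator) -> SuspensionSpec:
    """Random but physically sane suspension for property tests."""
    particle = ParticleSpec(
        core_diameter=float(rng.uniform(5e-9, 25e-9)),
        hydrodynamic_ratio=float(rng.uniform(1.0, 2.5)),
        anisotropy_constant=float(rng.uniform(5e3, 40e3)),
        core_saturation_magnetization=float(rng.uniform(1e5, 5e5)),
    )
    medium = MediumSpec(
        viscosity=float(rng.uniform(5e-4, 5e-3)),
        temperature=float(rng.uniform(280.0, 330.0)),
    )
    return SuspensionSpec(
        particle=particle, medium=medium, number_density=float(rng.uniform(1e18, 1e22))
    )


CONSTANTS = CONSTANTS  # re-export for tests
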