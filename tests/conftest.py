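import numpy as np
import pytest

from semdust.edx_measurement import BeamConfig
from semdust.particle_model import (
    Composition,
    Morphology,
    ParticleClass,
    ParticleRecord,
    ProtocolConfig,
)


@pytest.fixture
def protocol() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture
def beam() -> BeamConfig:
    return BeamConfig()


@pytest.fixture
def quiet_beam() -> BeamConfig:
    """Noise-free beam for exact-arithmetic checks."""
    return BeamConfig(noise_2sigma_atpct=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


def make_particle(
    pid: str = "p1",
    x: float = 0.0,
    y: float = 0.0,
    L: float = 10.0,
    thickness: float | None = 5.0,
    morphology: Morphology = Morphology.MINERAL_LIKE,
    particle_class: ParticleClass | None = ParticleClass.COAL,
    **atpct: float,
) -> ParticleRecord:
    comp = (
        Composition.from_atpct(**atpct)
        if atpct
        else Composition.from_atpct(C=83.0, O=14.0, Si=3.0)
    )
    return ParticleRecord(
        id=pid,
        x_mm=x,
        y_mm=y,
        L_um=L,
        morphology=morphology,
        intrinsic_composition=comp,
        particle_class=particle_class,
        thickness_um=thickness,
    )
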