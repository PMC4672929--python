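import numpy as np
import pytest

from chemoclust import presets
from chemoclust.params import (
    EnsembleParameters,
    ExpressionCondition,
    LinkerScheme,
)


@pytest.fixture(scope="session")
def tsr_params() -> EnsembleParameters:
    """Shared parameter set of the expression-variation model curves."""
    return presets.tsr_qeqe_params()


@pytest.fixture(scope="session")
def tar_qeqe_params() -> EnsembleParameters:
    """Tar-only QEQE parameter set (density rho = 10.30)."""
    return presets.tar_modification_params("QEQE")


@pytest.fixture(scope="session")
def wonly_params() -> EnsembleParameters:
    """CheW-only-linker model parameters (W family density)."""
    return presets.wonly_params("W")


@pytest.fixture(scope="session")
def zero_energy_params() -> EnsembleParameters:
    """All energies and potentials zero: every species weight is its
    multiplicity, making the ensemble hand-enumerable."""
    return EnsembleParameters.from_dict(
        dict(delta_eps=0.0, kd_on=1.0, kd_off=0.5, J=0.0,
             mu_w0=0.0, mu_a2_0=0.0, rho=7.2)
    )


@pytest.fixture(scope="session")
def wildtype() -> ExpressionCondition:
    return ExpressionCondition()


def random_parameter_draw(rng: np.random.Generator, scheme: LinkerScheme) -> EnsembleParameters:
    """One random but physically sensible parameter set."""
    kd_off = float(rng.uniform(1e-4, 0.05))
    return EnsembleParameters(
        mod=__import__("chemoclust").ModificationState(float(rng.uniform(-4.0, 0.5))),
        binding=__import__("chemoclust").LigandBinding(
            kd_on=float(rng.uniform(0.5, 20.0)), kd_off=kd_off
        ),
        j_coupling=float(rng.uniform(-5.0, 0.0)),
        mu_w0=float(rng.uniform(-3.0, 2.0)),
        mu_a2_0=float(rng.uniform(-3.0, 2.0)),
        mu_w2_0=float(rng.uniform(-6.0, 2.0)),
        rho_target=float(rng.uniform(0.5, 11.0)),
        x_max=4,
        scheme=scheme,
    )
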