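import pytest

from barmech.edl_core import ElectrolyteModel

NM = 1e-9


@pytest.fixture(scope="session")
def reference_model() -> ElectrolyteModel:
    """Physiological electrolyte: 0.15 mol/l salt, 55 mol/l water, 4.79 D."""
    return ElectrolyteModel.from_molar(0.15, 55.0, 4.79, 298.0)


@pytest.fixture(scope="session")
def reference_planar_profile(reference_model):
    """Converged self-consistent planar profile at sigma = 0.2 As/m^2.

    Session-scoped: several tests interrogate the same converged solution.
    """
    from barmech.edl_planar import solve_planar

    return solve_planar(reference_model, 0.2)
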