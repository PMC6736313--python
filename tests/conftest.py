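import numpy as np
import pytest

from memlipo import fixtures as fx
from memlipo import profiles as pf


@pytest.fixture(scope="session")
def raw_profiles():
    return fx.synth_raw_profiles(seed=11)


@pytest.fixture(scope="session")
def processed_kcal(raw_profiles):
    return pf.process_profiles(raw_profiles, to_reu=False)


@pytest.fixture(scope="session")
def processed_reu(raw_profiles):
    return pf.process_profiles(raw_profiles)


@pytest.fixture(scope="session")
def splines(processed_reu):
    return pf.build_splines(processed_reu)


@pytest.fixture
def helix_pdb(tmp_path):
    """Factory: build an ideal helix and return the written PDB path."""
    def _build(sequence="A" * 25, phi=-60.0, psi=-45.0, tilt=0.0,
               center_depth=0.0, name="helix.pdb"):
        helix = fx.build_helix(fx.HelixSpec(
            sequence=sequence, phi=phi, psi=psi, tilt=tilt,
            center_depth=center_depth))
        path = tmp_path / name
        fx.write_pdb(helix, path)
        return path
    return _build


@pytest.fixture
def flat_profile():
    """A constant-energy profile on the canonical 27-knot grid."""
    def _make(aa="L", value=1.0):
        return pf.InsertionProfile(aa, pf.DEPTHS_27.copy(),
                                   np.full(pf.N_KNOTS, float(value)))
    return _make
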