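import pytest

from phorep import profiles, synth


@pytest.fixture(scope="session")
def standard_proteome():
    """The standard synthetic proteome: 200 decoys, 1 PhoD + 4 PhoX implants."""
    return synth.gen_proteome(synth.ProteomeConfig(seed=1))


@pytest.fixture(scope="session")
def standard_calibrations(standard_proteome):
    """Gumbel calibrations for every PSSM of the standard family sets."""
    return {
        pssm.accession: profiles.calibrate(pssm, n_samples=1000, seed=10)
        for fs in standard_proteome.family_sets
        for pssm in fs.pssms
    }
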