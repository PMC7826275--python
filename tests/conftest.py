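import numpy as np
import pytest

import tandemcount as tc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def unit2k():
    """A 2-kb random repeat unit, the canonical array-unit size."""
    return tc.random_unit(2000, np.random.default_rng(101), id="unit2k")


@pytest.fixture(scope="session")
def flanks1k():
    """Unique 1-kb flanks."""
    return tc.random_flanks(1000, np.random.default_rng(202))


@pytest.fixture(scope="session")
def error8():
    """The default nanopore-like error regime: 3% sub + 2% ins + 3% del."""
    return tc.ErrorModel(0.03, 0.02, 0.03, seed=303)


@pytest.fixture(scope="session")
def clean():
    return tc.ErrorModel(0.0, 0.0, 0.0, seed=0)


def make_reads(unit, flanks, copy_number, model, n_reads, seed, **spec_kw):
    """Full-length (spanning) reads from one array spec, with truth."""
    spec = tc.ArraySpec(unit, copy_number, flanks, **spec_kw)
    molecule, truth = tc.build_array_molecule(spec, molecule_id=f"k{copy_number}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_reads):
        out.append(tc.simulate_read(molecule, truth, model, rng=rng, read_id=f"k{copy_number}_{i}"))
    return out
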