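import numpy as np
import pytest

from nescan.benchmark import load_table1_fixture
from nescan.structure import SamplingConfig, SurrogateEnergy, build_template_library
from nescan.synthetic import _SAFE_SPACERS, _motif_residues, match_from_registry


@pytest.fixture(scope="session")
def templates():
    return build_template_library("synthetic")


@pytest.fixture(scope="session")
def backend():
    return SurrogateEnergy()


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_by_name(table1):
    return {e.name: e for e in table1}


def make_ideal_peptide(class_id: str, seed: int, phi_residues=None):
    """One on-register peptide of the given class with safe flanks.

    Returns (sequence, phi positions ascending-in-registry-order, match).
    """
    rng = np.random.default_rng(seed)
    core, phi_off, _ = _motif_residues(class_id, rng, phi_residues)
    nfl = "".join(rng.choice(list(_SAFE_SPACERS), 4))
    cfl = "".join(rng.choice(list(_SAFE_SPACERS), 2))
    if class_id.endswith("-R"):
        seq = cfl + core + nfl
        phis = tuple(len(cfl) + o + 1 for o in phi_off)
    else:
        seq = nfl + core + cfl
        phis = tuple(4 + o + 1 for o in phi_off)
    return seq, phis, match_from_registry(seq, class_id, phis)


@pytest.fixture(scope="session")
def ideal_1a():
    return make_ideal_peptide("1a", 1, ("L", "L", "L", "L"))


@pytest.fixture()
def det_config():
    return SamplingConfig.deterministic()


@pytest.fixture()
def minimal_config():
    return SamplingConfig.minimal()
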