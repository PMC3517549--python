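import numpy as np
import pytest

from netsel.codon_model import CodonModelSpec, uniform_frequencies
from netsel.io import load_fixture_table
from netsel.simulate import simulate_codon_alignment
from netsel.tree import PhylogeneticTree


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture_table()


@pytest.fixture(scope="session")
def two_taxon_tree():
    return PhylogeneticTree.from_newick("(A:0.3,B:0.2);")


@pytest.fixture(scope="session")
def three_taxon_tree():
    return PhylogeneticTree.from_newick("((A:0.15,B:0.25):0.1,C:0.3);")


@pytest.fixture(scope="session")
def four_taxon_tree():
    return PhylogeneticTree.from_newick("((A:0.1,B:0.15):0.05,C:0.2,D:0.25);")


@pytest.fixture(scope="session")
def eight_taxon_tree():
    return PhylogeneticTree.from_newick(
        "((((A:0.05,B:0.05):0.05,C:0.1):0.05,(D:0.1,E:0.1):0.05):0.05,"
        "(F:0.15,G:0.1):0.05,H:0.2);"
    )


@pytest.fixture(scope="session")
def m0_spec():
    return CodonModelSpec("M0", kappa=2.0, omega_params={"omega": 0.5})


@pytest.fixture(scope="session")
def m1a_spec():
    return CodonModelSpec("M1a", kappa=2.0, omega_params={"p0": 0.6, "omega0": 0.2})


@pytest.fixture(scope="session")
def small_alignment(four_taxon_tree, m0_spec):
    """A 60-codon alignment simulated under M0 for fitting smoke tests."""
    return simulate_codon_alignment(four_taxon_tree, m0_spec, 60, seed=11)
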