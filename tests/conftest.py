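import numpy as np
import pytest

from dupsel.codonml import CodonModelSpec, SiteClass
from dupsel.seqio import Alignment, GeneticCode, parse_newick


@pytest.fixture(scope="session")
def code():
    return GeneticCode.standard()


@pytest.fixture()
def toy_alignment():
    return Alignment(["a", "b", "c", "d"], ["AAAA", "AAAT", "TAAA", "TAAT"])


@pytest.fixture(scope="session")
def six_taxon_tree():
    return parse_newick(
        "(((A:0.1,B:0.1):0.1,C:0.2):0.2,((D:0.1,E:0.1):0.1,F:0.2):0.2);"
    )


@pytest.fixture(scope="session")
def m0_data(six_taxon_tree):
    """A 300-codon alignment evolved under a single-omega model."""
    from dupsel.synthetic_data import simulate_codon_alignment

    spec = CodonModelSpec(kappa=2.0, codon_freqs="equal",
                          classes=(SiteClass(1.0, 0.3),))
    caln, rec = simulate_codon_alignment(six_taxon_tree, spec, 300, seed=11)
    return caln, rec, spec


def random_nt_alignment(rng, n=6, L=100, p_gap=0.0):
    bases = np.array(list("ACGT"))
    mat = bases[rng.integers(0, 4, size=(n, L))]
    if p_gap > 0:
        mat[rng.random(size=mat.shape) < p_gap] = "N"
    return Alignment([f"s{i}" for i in range(n)],
                     ["".join(row) for row in mat])
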