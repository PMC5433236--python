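import numpy as np
import pytest

from quatscreen import simulate as sim
from quatscreen.profile import ProfileModel


@pytest.fixture(scope="session")
def family():
    rng = np.random.default_rng(1234)
    return sim.make_family(rng, length=80, n_seeds=6, divergence=0.10, name="fam")


@pytest.fixture(scope="session")
def model(family):
    return ProfileModel.from_alignment(family.seeds)


def codon_for():
    """One fixed codon per amino acid (alphabetically smallest)."""
    from Bio.Data import CodonTable

    tab = CodonTable.unambiguous_dna_by_id[11]
    out = {}
    for codon, aa in sorted(tab.forward_table.items()):
        out.setdefault(aa, codon)
    return out


@pytest.fixture(scope="session")
def fixed_codons():
    return codon_for()
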