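"""Shared fixtures: a hand-traceable taxonomy and a small simulated reference set."""

import numpy as np
import pytest

from amplicon16s.preprocess import PRIMERS_V1V9, PrimerSet
from amplicon16s.simulate import make_reference_set
from amplicon16s.taxonomy import load_taxonomy

# Two phyla under Bacteria; Streptococcus carries two species, a strain and a
# no-rank clade; Bifidobacterium carries one species. All lineages are short
# enough to trace by hand.
TOY_TAXONOMY_TSV = """taxon_id\tparent_id\trank\tname
1\t1\troot\troot
2\t1\tdomain\tBacteria
10\t2\tphylum\tFirmicutes
11\t2\tphylum\tActinobacteria
20\t10\tclass\tBacilli
21\t11\tclass\tActinomycetia
30\t20\torder\tLactobacillales
31\t21\torder\tBifidobacteriales
40\t30\tfamily\tStreptococcaceae
41\t31\tfamily\tBifidobacteriaceae
50\t40\tgenus\tStreptococcus
51\t41\tgenus\tBifidobacterium
60\t50\tno_rank\tenvironmental clade
100\t50\tspecies\tStreptococcus mutans
101\t50\tspecies\tStreptococcus pyogenes
102\t51\tspecies\tBifidobacterium longum
103\t60\tspecies\tStreptococcus cryptus
110\t100\tstrain\tStreptococcus mutans UA159
"""


@pytest.fixture(scope="session")
def toy_taxonomy(tmp_path_factory):
    path = tmp_path_factory.mktemp("tax") / "toy.tsv"
    path.write_text(TOY_TAXONOMY_TSV)
    return load_taxonomy(tsv=path)


#: Same primers as the full-length assay but a window sized for short fixtures.
SMALL_PRIMERS = PrimerSet("small", PRIMERS_V1V9.fwd, PRIMERS_V1V9.rev, (300, 900))


@pytest.fixture(scope="session")
def small_refset():
    """Six species (one genus of two + singletons), ~440 bp references."""
    return make_reference_set(
        6,
        seed=5,
        genus_sizes=[2, 1, 1, 1, 1],
        interior_len=400,
        primers=SMALL_PRIMERS,
    )


@pytest.fixture(scope="session")
def small_db(small_refset):
    return small_refset.to_reference_db()


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
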