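import numpy as np
import pytest

from apestr.allele_caller import LocusDefinition
from apestr.str_model import Motif


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def toy_locus():
    """A tetranucleotide locus with distinctive anchor and flank."""
    return LocusDefinition(
        name="TOY1",
        anchor5="TTCGCCAGTCAGGTCCAATC",
        flank3="GGACCTAAGCTCATTGCAAT",
        motifs=(Motif("AATG"),),
        canonical=Motif("AATG"),
        region_range=(4, 80),
    )


@pytest.fixture
def compound_locus():
    return LocusDefinition(
        name="TOY2",
        anchor5="CATTGGCCTATACGAGACCA",
        flank3="TGCCAGATTACGTGGTCTCA",
        motifs=(Motif("GGAA"), Motif("GGCA")),
        canonical=Motif("GGAA"),
        region_range=(4, 120),
    )
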