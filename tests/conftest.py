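import pytest

from aspcr.seqio import SequenceRecord, SpeciesAlignment
from aspcr.synthetic_data import generate_alignment, paper_shaped_spec


@pytest.fixture
def tiny_alignment():
    """Four records, two species, one obvious diagnostic column (pos 3)."""
    return SpeciesAlignment(
        records=[
            SequenceRecord("a1", "SpA", "ACCTG"),
            SequenceRecord("a2", "SpA", "ACCTG"),
            SequenceRecord("b1", "SpB", "ACTTG"),
            SequenceRecord("b2", "SpB", "ACTTG"),
        ]
    )


@pytest.fixture
def fixture_alignment():
    """Paper-shaped synthetic alignment (8 species, 24 records, 574 bp)."""
    aln, truth = generate_alignment(paper_shaped_spec(seed=11))
    return aln, truth
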