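import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from gfd.core_io import GeneModel


def make_gene(
    gene_id: str,
    start: int,
    cds: str = "ATGAAATAA",
    species: str = "sp",
    chromosome: str = "chr1",
    introns=(),
) -> GeneModel:
    """Single-exon gene helper for coordinate-level tests."""
    return GeneModel(
        gene_id=gene_id,
        species=species,
        chromosome=chromosome,
        start=start,
        end=start + len(cds),
        strand="+",
        exons=[(start, start + len(cds))],
        cds_seq=cds,
        intron_positions_aa=list(introns),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
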