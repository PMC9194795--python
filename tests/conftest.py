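import numpy as np
import pandas as pd
import pytest

from xkin import AllelicCountMatrix, GeneAnnotation, PipelineConfig


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def small_matrix():
    """3 genes x 4 units (two replicate pairs), deterministic counts."""
    genes = pd.Index(["g1", "g2", "g3"], name="gene_id")
    units = pd.Index(["a_rep1", "a_rep2", "b_rep1", "b_rep2"], name="unit_id")
    a1 = pd.DataFrame(
        [[3, 2, 10, 10], [0, 0, 5, 5], [7, 8, 0, 1]], index=genes, columns=units
    )
    a2 = pd.DataFrame(
        [[7, 8, 10, 10], [10, 10, 5, 5], [3, 2, 9, 9]], index=genes, columns=units
    )
    return AllelicCountMatrix(counts_a1=a1, counts_a2=a2)


@pytest.fixture
def small_annotation():
    table = pd.DataFrame(
        {
            "chromosome": ["chrX", "chrX", "chr13"],
            "start": [100, 5000, 200],
            "end": [1100, 6000, 1200],
            "is_patch": [False, False, False],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return GeneAnnotation(table=table)
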