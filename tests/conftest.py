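import pandas as pd
import pytest

from memoryscan.expression import CountMatrix, GeneAnnotation, GeneModel


@pytest.fixture
def tiny_annotation() -> GeneAnnotation:
    """Four genes on two chromosomes, both strands, varied lengths."""
    return GeneAnnotation(
        [
            GeneModel("Alpha", "Alpha", "chr1", "+", 100_000, 1000),
            GeneModel("Beta", "Beta", "chr1", "-", 150_000, 2000),
            GeneModel("Gamma", "Gamma", "chr2", "+", 50_000, 500),
            GeneModel("Delta", "Delta", "chr2", "-", 120_000, 4000),
        ]
    )


@pytest.fixture
def tiny_counts(tiny_annotation) -> CountMatrix:
    counts = pd.DataFrame(
        {
            "ctrl": [1000, 30, 0, 400],
            "tnf": [4000, 30, 80, 100],
        },
        index=pd.Index(["Alpha", "Beta", "Gamma", "Delta"], name="gene_id"),
    )
    libs = pd.Series({"ctrl": 1e7, "tnf": 1e7})
    return CountMatrix(counts=counts, library_sizes=libs)
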