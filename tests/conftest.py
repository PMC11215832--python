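import numpy as np
import pytest

from banngp import GenotypeMatrix, VariantRecord


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """3 samples x 2 SNPs with known dosages."""
    return GenotypeMatrix(
        dosages=np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]),
        sample_ids=["s1", "s2", "s3"],
        variants=[
            VariantRecord("v1", "1", 100, "A", "B"),
            VariantRecord("v2", "1", 250, "A", "B"),
        ],
    )


def make_variants(positions, chrom="1"):
    """Variant records at the given positions on one chromosome."""
    return [
        VariantRecord(f"{chrom}_v{i}", chrom, int(p), "A", "B")
        for i, p in enumerate(positions)
    ]


@pytest.fixture
def variants_factory():
    return make_variants
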