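import numpy as np
import pandas as pd
import pytest

from growmark.simdata import SimulationConfig, simulate_genotypes
from growmark.variants import VariantTable


@pytest.fixture(scope="session")
def small_table() -> VariantTable:
    """90 individuals x 1000 loci under the default four-population design."""
    return simulate_genotypes(SimulationConfig(seed=42))


@pytest.fixture()
def tiny_table() -> VariantTable:
    """Hand-built 4-individual, 3-locus table with one missing call."""
    loci = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [100, 200, 150],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "C"],
        }
    )
    dosage = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 1.0, 0.0],
            [2.0, np.nan, 1.0],
            [2.0, 1.0, 0.0],
        ]
    )
    return VariantTable(
        loci=loci,
        dosage=dosage,
        samples=["s1", "s2", "s3", "s4"],
        populations=["P1", "P1", "P2", "P2"],
    )
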