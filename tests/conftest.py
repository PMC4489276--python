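import numpy as np
import pytest

from intercov.msa import Msa, SequenceRecord, SequenceWeights
from intercov.synthetic import (PlantedPottsSpec, cross_segment_pairs,
                                sample_potts_msa)


def make_msa(rows, taxids=None, ids=None):
    """Build an Msa from plain residue strings."""
    n = len(rows)
    taxids = taxids or [None] * n
    ids = ids or [f"s{k}" for k in range(n)]
    return Msa([SequenceRecord(i, r, t)
                for i, r, t in zip(ids, rows, taxids)])


def uniform_weights(msa):
    return SequenceWeights(np.ones(msa.n_records), float(msa.n_records))


@pytest.fixture(scope="session")
def planted_potts():
    """One planted-coupling Potts sample shared by the statistical tests:
    L=40, q=8, split 20, 10 cross-segment pairs of strength 1.5, n=2000."""
    spec = PlantedPottsSpec(planted_pairs=cross_segment_pairs(40, 20, 10, 1),
                            seed=1)
    paired, planted = sample_potts_msa(spec)
    return paired, planted


@pytest.fixture(scope="session")
def toy_msa6x4():
    """6-row, 4-column alignment with mixed conservation/covariation."""
    return make_msa(["ACDE", "ACDF", "AGHE", "AGHF", "ACDE", "AGHF"])
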