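import numpy as np
import pytest

from clonedelim.alignment_io import Alignment, LineagePartition


def make_alignment(seqs, ids=None, **kw):
    ids = ids or [f"s{i+1}" for i in range(len(seqs))]
    return Alignment(locus_name=kw.pop("locus_name", "toy"),
                     sample_ids=ids, sequences=[s.upper() for s in seqs], **kw)


@pytest.fixture
def toy_coding():
    # 9-column coding toy: two lineages with a diagnostic third-position
    # change GGA -> GGG (Gly/Gly, synonymous under the standard code)
    seqs = [
        "ATGGGAAAA",
        "ATGGGAAAA",
        "ATGGGGAAA",
        "ATGGGGAAA",
    ]
    return make_alignment(seqs, ids=["a1", "a2", "b1", "b2"],
                          coding=True, genetic_code_id="standard")


@pytest.fixture
def toy_partition():
    return LineagePartition({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_alignment(rng, n=6, L=300, p_gap=0.02):
    bases = np.array(list("ACGT-N"))
    probs = [0.3, 0.2, 0.2, 0.3 - p_gap, p_gap / 2, p_gap / 2]
    probs = np.array(probs) / np.sum(probs)
    seqs = ["".join(rng.choice(bases, size=L, p=probs)) for _ in range(n)]
    return make_alignment(seqs)
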