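import numpy as np
import pandas as pd
import pytest

from plastbarcode.seqio import Alignment, SampleTable

BASES = "ACGT"


def random_alignment(rng, n, L, gap_frac=0.0, n_frac=0.0) -> Alignment:
    mat = rng.integers(0, 4, size=(n, L))
    rows = []
    for i in range(n):
        chars = [BASES[b] for b in mat[i]]
        for j in range(L):
            u = rng.random()
            if u < gap_frac:
                chars[j] = "-"
            elif u < gap_frac + n_frac:
                chars[j] = "N"
        rows.append("".join(chars))
    ids = tuple(f"t{i}" for i in range(n))
    return Alignment(ids, tuple(rows))


def sample_table(rows) -> SampleTable:
    """rows: (sample_id, species, role, outgroup) tuples."""
    return SampleTable.from_frame(
        pd.DataFrame(rows, columns=["sample_id", "species", "role", "outgroup"])
    )


def random_topology_newick(rng, labels) -> str:
    """Random binary tree over labels by repeated pairwise joining."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
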