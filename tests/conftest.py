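"""Shared fixtures: small reference sets and toy OTU tables.

All fixture data is generated programmatically; nothing is loaded from disk.
"""

import numpy as np
import pytest

from ampliforge.otu_inference import Otu, OtuTable


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Introduce exactly n_subs substitutions at distinct positions."""
    arr = list(seq)
    for i in rng.choice(len(seq), size=n_subs, replace=False):
        arr[i] = [b for b in "ACGT" if b != arr[i]][rng.integers(0, 3)]
    return "".join(arr)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_table():
    """3 samples x 4 OTUs with hand-set counts."""
    counts = np.array(
        [
            [10, 5, 0, 1],
            [8, 6, 2, 0],
            [0, 0, 30, 4],
        ]
    )
    otus = tuple(
        Otu(otu_id=f"OTU_{j + 1}", centroid="ACGT" * 10, size=int(counts[:, j].sum()))
        for j in range(4)
    )
    return OtuTable(samples=("S1", "S2", "S3"), otus=otus, counts=counts)


@pytest.fixture(scope="session")
def small_reference_set():
    """Five genera x 3 reference sequences each, ~5% between-genus divergence."""
    rng = np.random.default_rng(7)
    refs = []
    genera = ["Aquifex", "Bacillus", "Clostridium", "Deinococcus", "Escherichia"]
    for g, genus in enumerate(genera):
        base = random_dna(rng, 500)
        for r in range(3):
            seq = mutate(rng, base, 5)  # within-genus ~1%
            lineage = (
                "Bacteria",
                f"Phylum{g % 2}",
                f"Class{g % 2}",
                f"Order{g // 2}",
                f"Family{g // 2}",
                genus,
            )
            refs.append((seq, lineage))
    return refs
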