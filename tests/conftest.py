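"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from barcodegap.distance import DistanceMatrix, K2P
from barcodegap.seq_model import LabeledAlignment
from barcodegap.synthetic_data import CommunitySpec, simulate_community


def matrix_from_condensed(condensed, ids=None, model=K2P) -> DistanceMatrix:
    """Fabricate a DistanceMatrix from upper-triangle values (testing only)."""
    condensed = np.asarray(condensed, dtype=float)
    m = condensed.size
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    assert n * (n - 1) // 2 == m, "condensed length must be n(n-1)/2"
    values = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    values[iu] = condensed
    values[(iu[1], iu[0])] = condensed
    if ids is None:
        ids = tuple(f"s{i}" for i in range(n))
    return DistanceMatrix(
        ids=tuple(ids),
        values=values,
        model=model,
        comparable_sites=np.full((n, n), 100, dtype=np.int64),
    )


def random_labeled_matrix(rng, n_max=30):
    """Random symmetric distance matrix with labels (every species >= 2 members)."""
    n_species = rng.integers(2, 5)
    sizes = rng.integers(2, 6, size=n_species)
    labels = []
    for k, s in enumerate(sizes):
        labels += [f"sp{k}"] * int(s)
    labels = labels[:n_max]
    n = len(labels)
    condensed = rng.random(n * (n - 1) // 2) * 0.3
    dm = matrix_from_condensed(condensed, ids=[f"q{i}" for i in range(n)])
    return dm, labels


@pytest.fixture
def toy_alignment() -> LabeledAlignment:
    return LabeledAlignment(
        ids=["a1", "a2", "b1", "b2"],
        seqs=["ACGTACGTAC", "ACGTACGTAC", "ACGTACGTGG", "ACGTACGTGG"],
        labels=["A", "A", "B", "B"],
    )


CLEAN_SPEC = CommunitySpec(
    n_species=4,
    per_species_n=(10, 10, 10, 10),
    seq_length=600,
    target_intra=0.01,
    target_inter=0.15,
    kappa=2.0,
    seed=7,
)


@pytest.fixture(scope="session")
def clean_community():
    """A well-separated 4-species community (fixed seed)."""
    return simulate_community(CLEAN_SPEC)


@pytest.fixture(scope="session")
def overlap_community():
    """Community with a haplotype shared between two species."""
    spec = CommunitySpec(
        n_species=3,
        per_species_n=(6, 6, 6),
        seq_length=600,
        target_intra=0.01,
        target_inter=0.15,
        kappa=2.0,
        overlap_mode=True,
        seed=11,
    )
    return simulate_community(spec)
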