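"""Molecular-diversity statistics: haplotypes, Hd, segregating sites, pi.

Haplotype calling uses complete deletion: alignment columns containing N or
a gap in *any* sequence are removed before sequences are compared for
identity, so haplotype membership is well defined. Nucleotide diversity, by
contrast, averages pairwise p-distances under pairwise deletion (each pair
keeps every column both members can be compared at).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict

import numpy as np

from .errors import DegenerateDataError, UndefinedDiversityError
from .distance import P_DIST, encode_sequences, pairwise_distance_matrix
from .seq_model import LabeledAlignment


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    n_haplotypes: int
    haplotype_diversity: float
    segregating_sites: int
    nucleotide_diversity: float

    def to_dict(self) -> dict:
        return asdict(self)


def _require_pairs(aln: LabeledAlignment) -> None:
    if aln.n < 2:
        raise DegenerateDataError(
            f"diversity statistics need >= 2 sequences, got {aln.n}"
        )


def haplotype_summary(aln: LabeledAlignment) -> tuple[int, float]:
    """Distinct-haplotype count and Nei & Tajima haplotype diversity.

    Hd = (n/(n-1)) * (1 - sum(p_i^2)) over haplotype relative frequencies
    p_i, with haplotypes defined on the columns free of N/- in every
    sequence.
    """
    _require_pairs(aln)
    codes = encode_sequences(aln.seqs)
    usable = (codes < 4).all(axis=0)
    if not usable.any():
        raise UndefinedDiversityError(
            "every alignment column contains an N or gap in some sequence"
        )
    core = codes[:, usable]
    haplotypes = Counter(map(bytes, core))
    n = aln.n
    # integer form of (n/(n-1)) * (1 - sum p_i^2): exact when all distinct
    ssq = sum(c * c for c in haplotypes.values())
    hd = (n * (n * n - ssq)) / ((n - 1) * n * n)
    return len(haplotypes), hd


def nucleotide_diversity(aln: LabeledAlignment) -> float:
    """Mean pairwise per-site difference proportion (pi) over all pairs."""
    _require_pairs(aln)
    dm = pairwise_distance_matrix(aln, model=P_DIST)
    if dm.exceptions:
        ex = dm.exceptions[0]
        raise UndefinedDiversityError(
            f"pi undefined: pair ({ex.id_a}, {ex.id_b}) has no comparable sites"
        )
    return float(dm.condensed().mean())


def segregating_sites(aln: LabeledAlignment) -> int:
    """Columns with >= 2 distinct bases from {A,C,G,T} (N/- ignored per column)."""
    _require_pairs(aln)
    codes = encode_sequences(aln.seqs)
    s = 0
    for col in codes.T:
        bases = np.unique(col[col < 4])
        if bases.size >= 2:
            s += 1
    return s


def diversity_summary(aln: LabeledAlignment) -> DiversitySummary:
    """All diversity statistics for one alignment."""
    n_hap, hd = haplotype_summary(aln)
    return DiversitySummary(
        n=aln.n,
        n_haplotypes=n_hap,
        haplotype_diversity=hd,
        segregating_sites=segregating_sites(aln),
        nucleotide_diversity=nucleotide_diversity(aln),
    )
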