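"""Pairwise genetic distances: Kimura 2-parameter and raw proportion distance.

Distances are computed under *pairwise deletion*: for each sequence pair,
only columns where both sequences carry one of A/C/G/T are compared
("comparable sites"); columns with N or a gap in either member are dropped
for that pair only. The per-pair comparable-site counts are retained on the
matrix so alternative deletion policies can be audited externally.

All distances are stored as proportions (substitutions per site); reporting
layers convert to percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyDatasetError, SaturationError, UndefinedDistanceError
from .seq_model import LabeledAlignment

K2P = "K2P"
P_DIST = "P_DIST"
Model = Literal["K2P", "P_DIST"]

# Base encoding chosen so transitions are cheap to detect: A=0, G=1, C=2, T=3
# puts each transition pair {A,G} / {C,T} in one "purine/pyrimidine" bucket
# (code >> 1), so a difference is a transition iff the buckets agree.
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3, "N": 4, "-": 5}
_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode aligned sequences as a (n, L) uint8 matrix (A=0 G=1 C=2 T=3 N=4 -=5)."""
    flat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[flat].reshape(len(seqs), -1)


def _site_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """Comparable sites, transition diffs, transversion diffs for one pair."""
    comparable = (a < 4) & (b < 4)
    diff = comparable & (a != b)
    ts = diff & ((a >> 1) == (b >> 1))
    n_diff = int(diff.sum())
    n_ts = int(ts.sum())
    return int(comparable.sum()), n_ts, n_diff - n_ts


def _k2p_from_counts(m: int, n_ts: int, n_tv: int, pair: str = "") -> float:
    if m == 0:
        raise UndefinedDistanceError(
            f"no comparable sites for pair {pair or '?'}"
        )
    p = n_ts / m
    q = n_tv / m
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined (saturation) for pair {pair or '?'}: "
            f"P={p:.4f}, Q={q:.4f}",
            p=p,
            q=q,
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _pair_arrays(seq_a: str, seq_b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(seq_a) != len(seq_b):
        raise DomainError(
            f"sequences have unequal lengths {len(seq_a)} != {len(seq_b)}"
        )
    return encode_sequences([seq_a, seq_b])


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance between two aligned sequences.

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q), with P and Q the
    transition- and transversion-difference proportions among comparable
    sites. Raises :class:`UndefinedDistanceError` if no sites are
    comparable and :class:`SaturationError` when a log argument is <= 0.
    """
    a, b = _pair_arrays(seq_a, seq_b)
    m, n_ts, n_tv = _site_counts(a, b)
    return _k2p_from_counts(m, n_ts, n_tv)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of comparable sites at which the two sequences differ."""
    a, b = _pair_arrays(seq_a, seq_b)
    m, n_ts, n_tv = _site_counts(a, b)
    if m == 0:
        raise UndefinedDistanceError("no comparable sites")
    return (n_ts + n_tv) / m


@dataclass(frozen=True)
class PairException:
    """Record of a pair whose distance could not be computed."""

    id_a: str
    id_b: str
    reason: str  # "saturation" | "no_comparable_sites"
    p: float | None = None
    q: float | None = None


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair site bookkeeping.

    ``values`` is n x n, symmetric, zero diagonal; undefined pairs (listed
    in ``exceptions``) hold NaN. ``comparable_sites`` counts the columns
    actually compared for each pair.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    model: str
    comparable_sites: np.ndarray
    exceptions: list[PairException] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in row-major (i < j) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def require_complete(self) -> None:
        """Raise if any pair is undefined (saturated / no comparable sites)."""
        if self.exceptions:
            ex = self.exceptions[0]
            raise UndefinedDistanceError(
                f"{len(self.exceptions)} undefined pair(s) in distance "
                f"matrix, e.g. ({ex.id_a}, {ex.id_b}): {ex.reason}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        """Square TSV with id header row and column."""
        df = self.to_dataframe()
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format="%.10g")


def pairwise_distance_matrix(
    aln: LabeledAlignment, model: Model = K2P
) -> DistanceMatrix:
    """Full symmetric distance matrix over an alignment.

    Saturated or incomparable pairs do not abort the computation: their
    entries are NaN and they are itemized in ``exceptions``.
    """
    if model not in (K2P, P_DIST):
        raise DomainError(f"unknown distance model {model!r}")
    if aln.n < 2:
        raise EmptyDatasetError("need at least 2 sequences for a distance matrix")
    codes = encode_sequences(aln.seqs)
    n = aln.n
    values = np.zeros((n, n), dtype=float)
    comp = np.zeros((n, n), dtype=np.int64)
    is_base = codes < 4
    exceptions: list[PairException] = []
    bucket = codes >> 1
    for i in range(n - 1):
        a = codes[i]
        rest = codes[i + 1 :]
        comparable = is_base[i] & is_base[i + 1 :]
        diff = comparable & (rest != a)
        ts = diff & (bucket[i + 1 :] == bucket[i])
        m = comparable.sum(axis=1)
        n_diff = diff.sum(axis=1)
        n_ts = ts.sum(axis=1)
        n_tv = n_diff - n_ts
        comp[i, i + 1 :] = m
        comp[i + 1 :, i] = m
        with np.errstate(divide="ignore", invalid="ignore"):
            if model == P_DIST:
                d = np.where(m > 0, n_diff / np.maximum(m, 1), np.nan)
            else:
                p = n_ts / np.maximum(m, 1)
                q = n_tv / np.maximum(m, 1)
                w1 = 1.0 - 2.0 * p - q
                w2 = 1.0 - 2.0 * q
                ok = (m > 0) & (w1 > 0) & (w2 > 0)
                d = np.where(
                    ok,
                    -0.5 * np.log(np.where(ok, w1, 1.0))
                    - 0.25 * np.log(np.where(ok, w2, 1.0)),
                    np.nan,
                )
        for k in np.flatnonzero(np.isnan(d)):
            j = i + 1 + int(k)
            if m[k] == 0:
                exceptions.append(
                    PairException(aln.ids[i], aln.ids[j], "no_comparable_sites")
                )
            else:
                exceptions.append(
                    PairException(
                        aln.ids[i],
                        aln.ids[j],
                        "saturation",
                        p=float(n_ts[k] / m[k]),
                        q=float(n_tv[k] / m[k]),
                    )
                )
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
    # on comparable diagonal: a sequence vs itself uses its own base count
    np.fill_diagonal(comp, is_base.sum(axis=1))
    return DistanceMatrix(
        ids=aln.ids,
        values=values,
        model=model,
        comparable_sites=comp,
        exceptions=exceptions,
    )
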