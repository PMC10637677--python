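"""Barcoding-gap descriptive statistics.

Per-sequence extremes (max distance to conspecifics, min distance to
heterospecifics) feed boxplot-style summaries; per-species tables give mean
and range of intra- and interspecific distances. A global gap exists when
the largest intraspecific distance is strictly below the smallest
interspecific distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NoIntraspecificPairsError, SingleSpeciesError
from .distance import DistanceMatrix
from .threshold import _check_square


@dataclass
class GapTable:
    """Per-sequence extremes, per-species distance summaries, overall stats."""

    per_sequence: pd.DataFrame  # id, species, max_intra, min_inter
    per_species: pd.DataFrame
    overall: dict  # mean/sd of the two per-sequence columns (sd: ddof=1)

    def write_species_tsv(self, path: str | Path) -> None:
        self.per_species.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def write_long_tsv(self, path: str | Path) -> None:
        """Long-format per-sequence table (sequence, type, value) for plotting."""
        long = self.per_sequence.melt(
            id_vars=["id", "species"],
            value_vars=["max_intra", "min_inter"],
            var_name="type",
            value_name="value",
        )
        long.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _validate(dist_matrix: DistanceMatrix, labels: Sequence[str]) -> np.ndarray:
    _check_square(dist_matrix, labels)
    labels = np.asarray(labels, dtype=object)
    if len(set(labels)) < 2:
        raise SingleSpeciesError(
            "interspecific distances need at least 2 species"
        )
    return labels


def per_sequence_extremes(
    dist_matrix: DistanceMatrix, labels: Sequence[str]
) -> pd.DataFrame:
    """Max conspecific and min heterospecific distance per sequence.

    Rows exist only for sequences whose species has >= 2 members (others
    have no intraspecific distance).
    """
    labels = _validate(dist_matrix, labels)
    values = dist_matrix.values
    counts = pd.Series(labels).value_counts()
    rows = []
    for i in range(dist_matrix.n):
        if counts[labels[i]] < 2:
            continue
        same = labels == labels[i]
        same[i] = False
        rows.append(
            {
                "id": dist_matrix.ids[i],
                "species": labels[i],
                "max_intra": float(values[i][same].max()),
                "min_inter": float(values[i][~same & (np.arange(dist_matrix.n) != i)].min()),
            }
        )
    if not rows:
        raise NoIntraspecificPairsError("every species is a singleton")
    return pd.DataFrame(rows)


def species_distance_table(
    dist_matrix: DistanceMatrix, labels: Sequence[str]
) -> pd.DataFrame:
    """Mean and range of intra- and interspecific distances per species.

    The interspecific column pools distances from the species' members to
    members of *all* other species. Species with a single member get NaN
    intraspecific statistics.
    """
    labels = _validate(dist_matrix, labels)
    values = dist_matrix.values
    rows = []
    for species in sorted(set(labels)):
        members = np.flatnonzero(labels == species)
        others = np.flatnonzero(labels != species)
        if len(members) >= 2:
            iu = np.triu_indices(len(members), k=1)
            intra = values[np.ix_(members, members)][iu]
            intra_stats = (float(intra.mean()), float(intra.min()), float(intra.max()))
        else:
            intra_stats = (np.nan, np.nan, np.nan)
        inter = values[np.ix_(members, others)].ravel()
        rows.append(
            {
                "species": species,
                "n": len(members),
                "intra_mean": intra_stats[0],
                "intra_min": intra_stats[1],
                "intra_max": intra_stats[2],
                "inter_mean": float(inter.mean()),
                "inter_min": float(inter.min()),
                "inter_max": float(inter.max()),
            }
        )
    return pd.DataFrame(rows)


def build_gap_table(
    dist_matrix: DistanceMatrix, labels: Sequence[str]
) -> GapTable:
    """Assemble per-sequence, per-species and overall gap statistics."""
    per_seq = per_sequence_extremes(dist_matrix, labels)
    per_species = species_distance_table(dist_matrix, labels)
    overall = {
        "max_intra_mean": float(per_seq["max_intra"].mean()),
        "max_intra_sd": float(per_seq["max_intra"].std(ddof=1)),
        "min_inter_mean": float(per_seq["min_inter"].mean()),
        "min_inter_sd": float(per_seq["min_inter"].std(ddof=1)),
    }
    return GapTable(per_sequence=per_seq, per_species=per_species, overall=overall)


def gap_exists(gap_table: GapTable) -> tuple[bool, tuple[float, float] | None]:
    """Global barcoding gap: max intraspecific < min interspecific.

    Returns (flag, (max_intra, min_inter)) with the interval only when the
    gap exists.
    """
    max_intra = float(gap_table.per_sequence["max_intra"].max())
    min_inter = float(gap_table.per_sequence["min_inter"].min())
    if max_intra < min_inter:
        return True, (max_intra, min_inter)
    return False, None
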