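"""Best-close-match (BCM) identification.

Each sequence is treated as an unknown query against all other sequences.
If its nearest neighbour lies farther than the threshold the query gets
``no_id``; otherwise the species of the nearest neighbour(s) (within a tie
tolerance) decide ``correct`` / ``incorrect`` / ``ambiguous``.

A strict mode is available in which *every* species found within the
threshold (not just at the nearest-neighbour distance) makes the query
ambiguous; it is off by default because it degenerates at large thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyDatasetError
from .distance import DistanceMatrix
from .threshold import (
    STATUS_AMBIGUOUS,
    STATUS_CORRECT,
    STATUS_INCORRECT,
    STATUS_NO_ID,
    _check_square,
)

STATUSES = (STATUS_CORRECT, STATUS_INCORRECT, STATUS_AMBIGUOUS, STATUS_NO_ID)

DEFAULT_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SequenceIdentification:
    """BCM outcome for one query sequence."""

    id: str
    species: str
    status: str
    nn_distance: float
    nn_species: tuple[str, ...]  # sorted species set at the deciding distance


@dataclass
class IdentificationReport:
    """Per-sequence BCM statuses plus summary counts and proportions."""

    per_sequence: list[SequenceIdentification]
    threshold: float
    tie_tol: float
    strict_ambiguity: bool = False
    counts: dict[str, int] = field(init=False)
    proportions: dict[str, float] = field(init=False)

    def __post_init__(self):
        n = len(self.per_sequence)
        self.counts = {
            s: sum(1 for r in self.per_sequence if r.status == s)
            for s in STATUSES
        }
        self.proportions = {s: c / n for s, c in self.counts.items()}

    @property
    def n(self) -> int:
        return len(self.per_sequence)

    def per_species(self) -> pd.DataFrame:
        """Status counts per true species (rows sum to the overall counts)."""
        rows = {}
        for rec in self.per_sequence:
            row = rows.setdefault(
                rec.species, {"species": rec.species, "n": 0, **{s: 0 for s in STATUSES}}
            )
            row["n"] += 1
            row[rec.status] += 1
        return pd.DataFrame(sorted(rows.values(), key=lambda r: r["species"]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.per_sequence],
                "species": [r.species for r in self.per_sequence],
                "status": [r.status for r in self.per_sequence],
                "nn_distance": [r.nn_distance for r in self.per_sequence],
                "nn_species": [",".join(r.nn_species) for r in self.per_sequence],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def best_close_match(
    dist_matrix: DistanceMatrix,
    labels: Sequence[str],
    t: float,
    tie_tol: float = DEFAULT_TIE_TOL,
    strict_ambiguity: bool = False,
) -> IdentificationReport:
    """Identify every sequence by its best close match at threshold ``t``.

    For query q with nearest-neighbour distance m (self excluded):

    * m > t: ``no_id``;
    * otherwise let S be the species of all sequences within ``tie_tol``
      of m (or, with ``strict_ambiguity``, all within t): S = {species(q)}
      -> ``correct``; multiple species in S -> ``ambiguous``; a single
      other species -> ``incorrect``.
    """
    if t < 0:
        raise DomainError(f"threshold must be >= 0, got {t}")
    if tie_tol < 0:
        raise DomainError(f"tie tolerance must be >= 0, got {tie_tol}")
    _check_square(dist_matrix, labels)
    n = dist_matrix.n
    if n < 2:
        raise EmptyDatasetError("best-close-match needs at least 2 sequences")
    labels_arr = np.asarray(labels, dtype=object)
    values = dist_matrix.values
    records: list[SequenceIdentification] = []
    for i in range(n):
        d = values[i].copy()
        d[i] = np.inf
        m = float(d.min())
        if m > t:
            nn_set = tuple(sorted(set(labels_arr[d == m])))
            records.append(
                SequenceIdentification(
                    dist_matrix.ids[i], labels_arr[i], STATUS_NO_ID, m, nn_set
                )
            )
            continue
        if strict_ambiguity:
            deciding = d <= t
        else:
            deciding = d <= m + tie_tol
        species_set = tuple(sorted(set(labels_arr[deciding])))
        if len(species_set) > 1:
            status = STATUS_AMBIGUOUS
        elif species_set[0] == labels_arr[i]:
            status = STATUS_CORRECT
        else:
            status = STATUS_INCORRECT
        records.append(
            SequenceIdentification(
                dist_matrix.ids[i], labels_arr[i], status, m, species_set
            )
        )
    return IdentificationReport(
        per_sequence=records,
        threshold=float(t),
        tie_tol=float(tie_tol),
        strict_ambiguity=strict_ambiguity,
    )


def summarize_identifications(
    report: IdentificationReport,
    other: IdentificationReport | None = None,
) -> pd.DataFrame:
    """Counts and proportions per species plus an overall row.

    With ``other`` given (a second report at a different threshold), the
    count columns are formatted as "a/b" pairs, one value per report,
    mirroring two-threshold comparison tables.
    """
    tables = [report.per_species().set_index("species")]
    if other is not None:
        if [r.id for r in other.per_sequence] != [r.id for r in report.per_sequence]:
            raise DomainError("reports to compare cover different sequences")
        tables.append(other.per_species().set_index("species"))
    out = pd.DataFrame(index=tables[0].index)
    out["n"] = tables[0]["n"]
    for status in STATUSES:
        if other is None:
            out[status] = tables[0][status]
            out[f"{status}_prop"] = tables[0][status] / tables[0]["n"]
        else:
            out[status] = [
                f"{a}/{b}" for a, b in zip(tables[0][status], tables[1][status])
            ]
    overall = {"n": report.n}
    for status in STATUSES:
        if other is None:
            overall[status] = report.counts[status]
            overall[f"{status}_prop"] = report.proportions[status]
        else:
            overall[status] = f"{report.counts[status]}/{other.counts[status]}"
    out.loc["OVERALL"] = pd.Series(overall)
    out = out.reset_index().rename(columns={"index": "species"})
    return out
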