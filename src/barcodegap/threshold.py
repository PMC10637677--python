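"""Species-delimitation threshold estimators.

Three estimators, all operating on a :class:`~barcodegap.distance.DistanceMatrix`:

* :func:`local_minima_threshold` — kernel-density dips in the pooled
  pairwise-distance distribution (no species labels needed);
* :func:`optimize_threshold` — grid search minimizing the cumulative
  identification error (false negatives + false positives) of
  :func:`threshold_id`;
* :func:`percentile_threshold` — the smallest observed intraspecific
  distance below which a given fraction (default 95%) of all intraspecific
  distances fall.

The package never adjudicates between estimators; it reports all of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import (
    DomainError,
    NoIntraspecificPairsError,
)
from .distance import DistanceMatrix

LOCAL_MINIMA = "LOCAL_MINIMA"
THRESH_OPT = "THRESH_OPT"
PERCENTILE_95 = "PERCENTILE_95"

#: Threshold grid 0.1%..2% in 0.1% steps.
DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 21) * 0.001, 10))

STATUS_CORRECT = "correct"
STATUS_INCORRECT = "incorrect"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NO_ID = "no_id"


@dataclass
class ThresholdEstimate:
    """A candidate species-delimitation cutoff plus method diagnostics.

    ``value`` is None when the method finds no threshold (e.g. a unimodal
    density). ``candidates`` holds every admissible threshold in ascending
    order; ``value`` is the smallest candidate.
    """

    method: str
    value: float | None
    candidates: tuple[float, ...]
    diagnostics: dict = field(default_factory=dict)

    @property
    def found(self) -> bool:
        return self.value is not None


def _check_square(dist_matrix: DistanceMatrix, labels: Sequence[str] | None):
    dist_matrix.require_complete()
    if labels is not None and len(labels) != dist_matrix.n:
        raise DomainError(
            f"{len(labels)} labels for a {dist_matrix.n}-sequence matrix"
        )


def local_minima_threshold(
    dist_matrix: DistanceMatrix,
    bw_method: str | float = "silverman",
    grid_size: int = 512,
) -> ThresholdEstimate:
    """Candidate thresholds from dips in the pairwise-distance density.

    A Gaussian KDE of all unordered pairwise distances is evaluated on a
    regular grid over [0, max distance]; every interior strict local
    minimum of the density is a candidate. If the density has no interior
    minimum (unimodal / degenerate), ``value`` is None.
    """
    _check_square(dist_matrix, None)
    d = dist_matrix.condensed()
    diagnostics: dict = {"bw_method": bw_method, "grid_size": grid_size}
    if len(np.unique(d)) < 2:
        diagnostics["note"] = "degenerate: fewer than 2 distinct distances"
        return ThresholdEstimate(LOCAL_MINIMA, None, (), diagnostics)
    kde = gaussian_kde(d, bw_method=bw_method)
    xs = np.linspace(0.0, float(d.max()), grid_size)
    ys = kde(xs)
    interior = (ys[1:-1] < ys[:-2]) & (ys[1:-1] < ys[2:])
    candidates = tuple(float(x) for x in xs[1:-1][interior])
    diagnostics["grid"] = xs
    diagnostics["density"] = ys
    diagnostics["bandwidth"] = float(kde.factor * d.std(ddof=1))
    value = min(candidates) if candidates else None
    return ThresholdEstimate(LOCAL_MINIMA, value, candidates, diagnostics)


@dataclass
class ThresholdIdResult:
    """Per-sequence statuses and confusion counts at one threshold."""

    threshold: float
    statuses: tuple[str, ...]
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def cumulative_error(self) -> int:
        return self.fn + self.fp


def threshold_id(
    dist_matrix: DistanceMatrix, labels: Sequence[str], t: float
) -> ThresholdIdResult:
    """Classify every sequence by its within-threshold neighbourhood.

    For each query, consider all other sequences at distance <= t:
    none -> ``no_id``; all conspecific -> ``correct``; all heterospecific
    -> ``incorrect``; mixed -> ``ambiguous``. Counts: TP = correct,
    FN = no_id, FP = incorrect + ambiguous, TN = n - TP - FN - FP.
    """
    if t < 0:
        raise DomainError(f"threshold must be >= 0, got {t}")
    _check_square(dist_matrix, labels)
    labels = np.asarray(labels, dtype=object)
    n = dist_matrix.n
    values = dist_matrix.values
    statuses = []
    for i in range(n):
        within = values[i] <= t
        within[i] = False
        if not within.any():
            statuses.append(STATUS_NO_ID)
            continue
        neighbour_labels = labels[within]
        conspecific = neighbour_labels == labels[i]
        if conspecific.all():
            statuses.append(STATUS_CORRECT)
        elif not conspecific.any():
            statuses.append(STATUS_INCORRECT)
        else:
            statuses.append(STATUS_AMBIGUOUS)
    tp = statuses.count(STATUS_CORRECT)
    fn = statuses.count(STATUS_NO_ID)
    fp = statuses.count(STATUS_INCORRECT) + statuses.count(STATUS_AMBIGUOUS)
    return ThresholdIdResult(
        threshold=float(t),
        statuses=tuple(statuses),
        tp=tp,
        fn=fn,
        fp=fp,
        tn=n - tp - fn - fp,
    )


def optimize_threshold(
    dist_matrix: DistanceMatrix,
    labels: Sequence[str],
    grid: Sequence[float] | None = None,
) -> ThresholdEstimate:
    """Grid search for the threshold minimizing cumulative error (FN + FP).

    ``candidates`` are all grid points attaining the minimum; ``value`` is
    the smallest of them. The full error table is kept in
    ``diagnostics["table"]`` (a DataFrame mirroring a cumulative-error
    barplot: threshold, tp, fn, fp, tn, cumulative_error).
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = [float(g) for g in grid]
    if not grid:
        raise DomainError("threshold grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise DomainError("threshold grid must be strictly increasing")
    rows = []
    for t in grid:
        res = threshold_id(dist_matrix, labels, t)
        rows.append(
            {
                "threshold": t,
                "tp": res.tp,
                "fn": res.fn,
                "fp": res.fp,
                "tn": res.tn,
                "cumulative_error": res.cumulative_error,
            }
        )
    table = pd.DataFrame(rows)
    min_err = int(table["cumulative_error"].min())
    candidates = tuple(
        float(t)
        for t in table.loc[table["cumulative_error"] == min_err, "threshold"]
    )
    return ThresholdEstimate(
        THRESH_OPT,
        min(candidates),
        candidates,
        {"table": table, "min_cumulative_error": min_err},
    )


def intraspecific_distances(
    dist_matrix: DistanceMatrix, labels: Sequence[str]
) -> np.ndarray:
    """All unordered conspecific pairwise distances (reserved labels excluded upstream)."""
    _check_square(dist_matrix, labels)
    labels = np.asarray(labels, dtype=object)
    iu = np.triu_indices(dist_matrix.n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    return dist_matrix.values[iu][same]


def interspecific_distances(
    dist_matrix: DistanceMatrix, labels: Sequence[str]
) -> np.ndarray:
    """All unordered heterospecific pairwise distances."""
    _check_square(dist_matrix, labels)
    labels = np.asarray(labels, dtype=object)
    iu = np.triu_indices(dist_matrix.n, k=1)
    diff = labels[iu[0]] != labels[iu[1]]
    return dist_matrix.values[iu][diff]


def percentile_threshold(
    dist_matrix: DistanceMatrix,
    labels: Sequence[str],
    coverage: float = 0.95,
) -> ThresholdEstimate:
    """Smallest observed intraspecific distance covering >= ``coverage`` of them.

    Returns the smallest intraspecific distance v such that the fraction of
    intraspecific distances <= v is at least ``coverage``.
    """
    if not 0.0 < coverage <= 1.0:
        raise DomainError(f"coverage must be in (0, 1], got {coverage}")
    intra = np.sort(intraspecific_distances(dist_matrix, labels))
    if intra.size == 0:
        raise NoIntraspecificPairsError(
            "no intraspecific pairs: every species is a singleton"
        )
    k = max(1, math.ceil(coverage * intra.size - 1e-12))
    value = float(intra[k - 1])
    return ThresholdEstimate(
        PERCENTILE_95,
        value,
        (value,),
        {
            "coverage": coverage,
            "n_intraspecific": int(intra.size),
            "achieved_coverage": float(np.mean(intra <= value)),
        },
    )
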