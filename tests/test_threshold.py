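import numpy as np
import pytest
from scipy.stats import gaussian_kde

from barcodegap.distance import pairwise_distance_matrix
from barcodegap.errors import DomainError, NoIntraspecificPairsError
from barcodegap.threshold import (
    DEFAULT_GRID,
    LOCAL_MINIMA,
    PERCENTILE_95,
    THRESH_OPT,
    interspecific_distances,
    intraspecific_distances,
    local_minima_threshold,
    optimize_threshold,
    percentile_threshold,
    threshold_id,
)

from conftest import matrix_from_condensed


def oracle_threshold_statuses(values, labels, t):
    """Brute-force neighbour-set classification."""
    n = len(labels)
    statuses = []
    for i in range(n):
        neighbours = [j for j in range(n) if j != i and values[i][j] <= t]
        if not neighbours:
            statuses.append("no_id")
        elif all(labels[j] == labels[i] for j in neighbours):
            statuses.append("correct")
        elif all(labels[j] != labels[i] for j in neighbours):
            statuses.append("incorrect")
        else:
            statuses.append("ambiguous")
    return statuses


class TestLocalMinima:
    def test_bimodal_single_dip(self):
        # 50 distances near 0.01, 55 near 0.20 (n=15 -> 105 pairs)
        condensed = np.array([0.01] * 50 + [0.20] * 55)
        dm = matrix_from_condensed(condensed)
        est = local_minima_threshold(dm)
        assert est.method == LOCAL_MINIMA
        assert len(est.candidates) == 1
        assert 0.01 < est.value < 0.20
        # independent oracle: dense KDE grid, sign-change scan
        kde = gaussian_kde(condensed, bw_method="silverman")
        xs = np.linspace(0, condensed.max(), 10_000)
        ys = kde(xs)
        sign_changes = np.flatnonzero(
            (np.diff(ys)[:-1] < 0) & (np.diff(ys)[1:] > 0)
        )
        assert len(sign_changes) == 1
        oracle_min = xs[sign_changes[0] + 1]
        assert est.value == pytest.approx(oracle_min, abs=0.01)

    def test_all_equal_no_threshold(self):
        dm = matrix_from_condensed(np.full(10, 0.05))
        est = local_minima_threshold(dm)
        assert est.value is None
        assert est.candidates == ()

    def test_clean_gap_candidate_inside_gap(self, clean_community):
        aln, _ = clean_community
        dm = pairwise_distance_matrix(aln)
        est = local_minima_threshold(dm)
        intra = intraspecific_distances(dm, aln.labels)
        inter = interspecific_distances(dm, aln.labels)
        assert est.value is not None
        assert intra.max() < est.value < inter.min()


class TestThresholdId:
    def test_two_identical_conspecifics(self):
        dm = matrix_from_condensed([0.0])
        res = threshold_id(dm, ["A", "A"], 0.01)
        assert res.statuses == ("correct", "correct")
        assert res.cumulative_error == 0

    def test_zero_threshold_heterospecific_at_zero(self):
        # a-b distance 0 but different species; a-c conspecific at 0.1
        dm = matrix_from_condensed([0.0, 0.1, 0.1], ids=["a", "b", "c"])
        res = threshold_id(dm, ["A", "B", "A"], 0.0)
        assert res.statuses[0] == "incorrect"
        assert res.statuses[1] == "incorrect"
        assert res.statuses[2] == "no_id"

    def test_negative_threshold(self):
        dm = matrix_from_condensed([0.1])
        with pytest.raises(DomainError):
            threshold_id(dm, ["A", "A"], -0.1)

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(0)
        from conftest import random_labeled_matrix

        for _ in range(30):
            dm, labels = random_labeled_matrix(rng)
            t = float(rng.random() * 0.3)
            res = threshold_id(dm, labels, t)
            assert list(res.statuses) == oracle_threshold_statuses(
                dm.values, labels, t
            )
            assert res.tp + res.fn + res.fp + res.tn == dm.n

    def test_no_id_monotone_in_t(self, clean_community):
        aln, _ = clean_community
        dm = pairwise_distance_matrix(aln)
        previous = dm.n + 1
        for t in np.linspace(0, dm.values.max(), 15):
            res = threshold_id(dm, aln.labels, t)
            assert res.fn <= previous
            previous = res.fn
        assert previous == 0  # t >= max distance leaves nothing unidentified

    def test_clean_gap_errors(self, clean_community):
        aln, _ = clean_community
        dm = pairwise_distance_matrix(aln)
        intra = intraspecific_distances(dm, aln.labels)
        inter = interspecific_distances(dm, aln.labels)
        inside = (intra.max() + inter.min()) / 2
        assert threshold_id(dm, aln.labels, inside).cumulative_error == 0
        assert threshold_id(dm, aln.labels, inter.min()).cumulative_error > 0


class TestOptimizeThreshold:
    def test_default_grid_mirrors_published_sweep(self):
        assert DEFAULT_GRID[0] == pytest.approx(0.001)
        assert DEFAULT_GRID[-1] == pytest.approx(0.020)
        assert len(DEFAULT_GRID) == 20
        steps = np.diff(DEFAULT_GRID)
        assert np.allclose(steps, 0.001)

    def test_clean_gap_candidates(self, clean_community):
        aln, _ = clean_community
        dm = pairwise_distance_matrix(aln)
        grid = [float(g) for g in np.round(np.arange(1, 41) * 0.005, 10)]
        est = optimize_threshold(dm, aln.labels, grid=grid)
        assert est.method == THRESH_OPT
        # oracle: brute-force cumulative error at each grid point
        errors = {
            t: sum(
                s in ("no_id", "incorrect", "ambiguous")
                for s in oracle_threshold_statuses(dm.values, aln.labels, t)
            )
            for t in grid
        }
        best = min(errors.values())
        expected_candidates = tuple(t for t in grid if errors[t] == best)
        assert est.candidates == expected_candidates
        assert est.value == expected_candidates[0]
        table = est.diagnostics["table"]
        assert (
            table["cumulative_error"].min()
            == table.loc[table["threshold"] == est.value, "cumulative_error"].item()
        )

    def test_single_point_grid(self):
        dm = matrix_from_condensed([0.0])
        est = optimize_threshold(dm, ["A", "A"], grid=[0.01])
        assert est.value == 0.01
        assert est.candidates == (0.01,)

    def test_grid_must_increase(self):
        dm = matrix_from_condensed([0.0])
        with pytest.raises(DomainError):
            optimize_threshold(dm, ["A", "A"], grid=[0.02, 0.01])
        with pytest.raises(DomainError):
            optimize_threshold(dm, ["A", "A"], grid=[])


class TestPercentileThreshold:
    def _matrix_with_intra(self, intra_values):
        # two species of 5: 10 intra pairs each; inter pairs set large
        n = 10
        labels = ["A"] * 5 + ["B"] * 5
        values = np.full((n, n), 0.9)
        np.fill_diagonal(values, 0.0)
        iu = np.triu_indices(n, k=1)
        intra_iter = iter(intra_values)
        for a, b in zip(*iu):
            if labels[a] == labels[b]:
                v = next(intra_iter)
                values[a, b] = values[b, a] = v
        dm = matrix_from_condensed(values[iu], ids=[f"s{i}" for i in range(n)])
        return dm, labels

    def test_twenty_value_ladder(self):
        intra = [round(0.01 * k, 10) for k in range(1, 21)]
        dm, labels = self._matrix_with_intra(intra)
        est = percentile_threshold(dm, labels, coverage=0.95)
        assert est.method == PERCENTILE_95
        assert est.value == pytest.approx(0.19)

    def test_all_equal(self):
        dm, labels = self._matrix_with_intra([0.03] * 20)
        est = percentile_threshold(dm, labels)
        assert est.value == pytest.approx(0.03)

    def test_full_coverage_is_max(self):
        intra = [round(0.01 * k, 10) for k in range(1, 21)]
        dm, labels = self._matrix_with_intra(intra)
        est = percentile_threshold(dm, labels, coverage=1.0)
        assert est.value == pytest.approx(0.20)

    def test_sort_and_scan_oracle(self):
        rng = np.random.default_rng(9)
        intra = sorted(rng.random(20) * 0.1)
        dm, labels = self._matrix_with_intra(intra)
        for coverage in (0.5, 0.8, 0.95, 1.0):
            est = percentile_threshold(dm, labels, coverage=coverage)
            # oracle: scan cumulative fraction over sorted values
            expected = next(
                v
                for k, v in enumerate(intra, start=1)
                if k / len(intra) >= coverage - 1e-12
            )
            assert est.value == pytest.approx(expected)

    def test_no_intraspecific_pairs(self):
        dm = matrix_from_condensed([0.1, 0.2, 0.3], ids=["a", "b", "c"])
        with pytest.raises(NoIntraspecificPairsError):
            percentile_threshold(dm, ["A", "B", "C"])

    def test_bad_coverage(self):
        dm = matrix_from_condensed([0.1])
        with pytest.raises(DomainError):
            percentile_threshold(dm, ["A", "A"], coverage=0.0)


class TestEstimatorAgreementOnCleanGap:
    def test_all_three_zero_error(self, clean_community):
        aln, _ = clean_community
        dm = pairwise_distance_matrix(aln)
        grid = [float(g) for g in np.round(np.arange(1, 41) * 0.005, 10)]
        values = [
            local_minima_threshold(dm).value,
            optimize_threshold(dm, aln.labels, grid=grid).value,
            percentile_threshold(dm, aln.labels).value,
        ]
        for v in values:
            assert v is not None
            assert threshold_id(dm, aln.labels, v).cumulative_error == 0
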