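"""Classical baselines: ROI scores, rank tests, regression, paired CBP."""

import numpy as np
import pandas as pd
import pytest

import lmmcbp as L
from lmmcbp.classical import (
    cbp_ttest,
    high_low_labels,
    rank_tests,
    regression_n400,
    subject_condition_scores,
    window_roi_average,
)

from .conftest import make_epochs


class TestWindowRoiAverage:
    def test_constant_epoch(self):
        ep = make_epochs(np.full((3, 4, 12), 5.0))
        scores = window_roi_average(ep, ep.electrodes[:2], L.TimeWindow(0.0, 200.0))
        assert np.allclose(scores, 5.0)

    def test_single_sample_roi_identity(self):
        ep = make_epochs(np.arange(12, dtype=float).reshape(1, 1, 12))
        s = window_roi_average(ep, ep.electrodes, L.TimeWindow(0.0, 50.0))
        # the window [0, 50) contains exactly the sample at 0 ms (index 2)
        assert s[0] == ep.amplitudes[0, 0, 2]

    def test_checkerboard_cancels(self):
        amps = np.zeros((1, 2, 12))
        amps[0, 0] = [1, -1] * 6
        amps[0, 1] = [-1, 1] * 6
        ep = make_epochs(amps)
        s = window_roi_average(ep, ep.electrodes, L.TimeWindow(-100.0, 100.0))
        assert s[0] == pytest.approx(0.0)

    def test_empty_roi_errors(self):
        ep = make_epochs(np.zeros((1, 2, 12)))
        with pytest.raises(ValueError):
            window_roi_average(ep, [], L.TimeWindow(0.0, 100.0))


class TestRankTests:
    def test_kruskal_hand_fixture(self):
        """Groups {1,2},{3,4},{5,6}: rank sums 3/7/11 give
        H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 4.5714..."""
        cells = pd.DataFrame({"g1": [1, 2], "g2": [3, 4], "g3": [5, 6]})
        res = rank_tests(cells, "k_level")
        assert res["statistic"] == pytest.approx(32 / 7, rel=1e-12)

    def test_kruskal_identical_groups(self):
        cells = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        res = rank_tests(cells, "k_level")
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_wilcoxon_perfect_separation_n6(self):
        """All six paired differences positive: exact two-sided p = 2/2^6."""
        cells = pd.DataFrame({"a": np.arange(6) + 10.0, "b": np.arange(6) + 1.0})
        res = rank_tests(cells, "paired_two_level")
        assert res["p"] == pytest.approx(0.03125)

    def test_missing_cell_raises(self):
        cells = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="incomplete"):
            rank_tests(cells, "paired_two_level")


class TestRegressionN400:
    def _data(self, beta, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {
                "subject_id": rng.choice([f"S{i}" for i in range(10)], n),
                "predictability": rng.normal(size=n),
            }
        )
        offsets = {f"S{i}": rng.normal(0, 3) for i in range(10)}
        scores = (
            beta * table["predictability"].to_numpy()
            + table["subject_id"].map(offsets).to_numpy()
            + rng.normal(0, 2, n)
        )
        return scores, table

    def test_null_slope_near_zero(self):
        scores, table = self._data(0.0, seed=1)
        res = regression_n400(scores, table)
        assert abs(res["beta"]) < 3 * res["se"]
        assert res["partial_r2"] < 0.01

    def test_recovers_slope_within_3_se(self):
        scores, table = self._data(1.5, seed=2)
        res = regression_n400(scores, table)
        assert abs(res["beta"] - 1.5) < 3 * res["se"]
        assert res["p"] < 1e-6

    def test_subject_offsets_absorbed_exactly(self):
        scores, table = self._data(1.0, n=400, seed=3)
        res1 = regression_n400(scores, table)
        shifted = scores + np.where(table["subject_id"] == "S3", 42.0, 0.0)
        res2 = regression_n400(shifted, table)
        assert res2["beta"] == pytest.approx(res1["beta"], rel=1e-9)


class TestHighLow:
    def test_outer_terciles_only(self):
        labels = high_low_labels(np.arange(9.0))
        assert list(labels[:3]) == ["low"] * 3
        assert list(labels[3:6]) == [None] * 3
        assert list(labels[6:]) == ["high"] * 3


class TestCbpTtest:
    def _paired_data(self, effect, seed=0, n_subj=6, n_per=20, n_el=6, n_ti=10):
        rng = np.random.default_rng(seed)
        amps, rows = [], []
        tid = 0
        for s in range(n_subj):
            for cond in ("A", "B"):
                for _ in range(n_per):
                    x = rng.normal(0, 1.0, size=(n_el, n_ti))
                    if cond == "B":
                        x[1:5, 3:8] += effect
                    amps.append(x)
                    rows.append({"trial_id": tid, "subject_id": f"S{s}", "cond": cond})
                    tid += 1
        ep = make_epochs(np.stack(amps))
        edges = [(f"E{i + 1:02d}", f"E{i + 2:02d}") for i in range(n_el - 1)]
        adj = L.adjacency_from_edges(edges, electrodes=ep.electrodes)
        return ep, pd.DataFrame(rows), adj

    def test_identical_conditions_no_clusters(self):
        ep, table, adj = self._paired_data(0.0, seed=4)
        ep.amplitudes[:] = 1.0  # exactly equal condition means
        res = cbp_ttest(ep, table, "cond", adj, n_permutations=20, seed=1)
        assert res.clusters.clusters == []

    def test_injected_effect_found_with_floor_p(self):
        ep, table, adj = self._paired_data(1.5, seed=5)
        res = cbp_ttest(ep, table, "cond", adj, n_permutations=100, seed=2)
        sig = res.significant(alpha=0.05)
        assert sig, "expected a significant cluster"
        support = np.zeros((6, 10), dtype=bool)
        support[1:5, 3:8] = True
        assert sig[0].overlap_fraction(support) >= 0.8
        assert res.clusters.p_values[0] == pytest.approx(1 / 100)
        assert res.clusters.is_bound[0]

    def test_label_swap_antisymmetry(self):
        ep, table, adj = self._paired_data(1.0, seed=6)
        res1 = cbp_ttest(ep, table, "cond", adj, n_permutations=30, seed=3)
        swapped = table.copy()
        swapped["cond"] = swapped["cond"].map({"A": "B", "B": "A"})
        res2 = cbp_ttest(ep, swapped, "cond", adj, n_permutations=30, seed=3)
        assert np.allclose(res1.t_map, -res2.t_map)
        m1 = sorted(round(c.mass, 9) for c in res1.clusters.clusters)
        m2 = sorted(round(-c.mass, 9) for c in res2.clusters.clusters)
        assert m1 == m2
        assert sorted(res1.clusters.p_values) == sorted(res2.clusters.p_values)

    def test_subject_missing_level_excluded(self):
        ep, table, adj = self._paired_data(0.5, seed=7)
        table = table.copy()
        table.loc[table.subject_id == "S0", "cond"] = "A"  # S0 lacks B
        with pytest.warns(UserWarning, match="lacks"):
            res = cbp_ttest(ep, table, "cond", adj, n_permutations=10, seed=4)
        assert res.n_subjects == 5
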