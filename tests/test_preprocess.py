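"""Epoch/word preprocessing: baseline, rejection, word filters, transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lmmcbp as L
from .conftest import make_epochs


class TestBaselineCorrect:
    def test_constant_epoch_becomes_zero(self):
        ep = make_epochs(np.full((2, 3, 12), 10.0))
        out = L.baseline_correct(ep)
        assert np.allclose(out.amplitudes, 0.0)

    def test_only_offending_electrode_shifted(self):
        amps = np.zeros((1, 3, 12))
        amps[0, 1, 0] = 3.0  # one baseline sample (-100 ms) of electrode 2
        ep = make_epochs(amps)
        out = L.baseline_correct(ep, L.TimeWindow(-100.0, 0.0))
        # window holds the samples at -100 and -50 ms: mean 1.5 subtracted
        # from electrode 2's whole trace, other electrodes untouched
        assert np.allclose(out.amplitudes[0, 0], 0.0)
        assert np.allclose(out.amplitudes[0, 2], 0.0)
        assert out.amplitudes[0, 1, 0] == pytest.approx(1.5)
        assert np.allclose(out.amplitudes[0, 1, 1:], -1.5)

    def test_default_window_zeroes_baseline_mean(self, small_dataset):
        epochs, _ = small_dataset
        mask = epochs.time_mask(L.TimeWindow(-100.0, 0.0))
        means = epochs.amplitudes[:, :, mask].mean(axis=2)
        assert np.allclose(means, 0.0, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.normal(size=(4, 3, 12)))
        once = L.baseline_correct(ep)
        twice = L.baseline_correct(once)
        assert np.allclose(once.amplitudes, twice.amplitudes, atol=1e-9)

    def test_window_outside_span_raises(self):
        ep = make_epochs(np.zeros((1, 2, 12)))
        with pytest.raises(L.InvalidWindowError):
            L.baseline_correct(ep, L.TimeWindow(-500.0, -400.0))


class TestRejectEpochs:
    def _table(self, n):
        return pd.DataFrame({"trial_id": np.arange(n)})

    def test_six_offending_electrodes_rejected(self):
        amps = np.zeros((1, 8, 12))
        amps[0, :6, 5] = 90.0
        ep = make_epochs(amps)
        out, table, log = L.reject_epochs(ep, self._table(1))
        assert out.n_trials == 0 and log.n_rejected == 1
        assert log.bad_electrode_counts[0] == 6

    def test_exactly_five_kept(self):
        amps = np.zeros((1, 8, 12))
        amps[0, :5, 5] = -90.0  # negative excursions count too
        ep = make_epochs(amps)
        out, _, log = L.reject_epochs(ep, self._table(1))
        assert out.n_trials == 1 and log.n_rejected == 0

    def test_all_zero_no_rejection(self):
        ep = make_epochs(np.zeros((5, 8, 12)))
        out, table, log = L.reject_epochs(ep, self._table(5))
        assert out.n_trials == 5 and log.n_rejected == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng.normal(0, 50, size=(40, 8, 12)))
        table = self._table(40)
        kept = [
            L.reject_epochs(ep, table, amp_threshold_uv=thr)[0].n_trials
            for thr in (40.0, 60.0, 80.0, 120.0)
        ]
        assert kept == sorted(kept)

    def test_alignment_preserved(self):
        rng = np.random.default_rng(4)
        ep = make_epochs(rng.normal(0, 60, size=(30, 8, 12)))
        table = pd.DataFrame({"trial_id": np.arange(30), "x": rng.normal(size=30)})
        out, tab, _ = L.reject_epochs(ep, table)
        assert np.array_equal(out.trial_ids, tab["trial_id"].to_numpy())


class TestFilterWords:
    def _table(self):
        return pd.DataFrame(
            {
                "trial_id": range(5),
                "pos_tag": ["noun", "noun", "determiner", "noun", "verb"],
                "word_length": [2, 4, 4, 4, 6],
                "position": [3, 1, 3, 3, 4],
            }
        )

    def test_rule_table(self):
        out = L.filter_words(self._table())
        # short noun out, sentence-initial noun out, determiner out
        assert out["trial_id"].tolist() == [3, 4]

    def test_missing_pos_tag_raises(self):
        t = self._table()
        t.loc[2, "pos_tag"] = None
        with pytest.raises(ValueError, match="pos_tag"):
            L.filter_words(t)


class TestLogitPredictability:
    def test_midpoint_is_zero(self):
        assert L.logit_predictability(0.5, 18) == pytest.approx(0.0)
        assert L.logit_predictability(0.5, 7) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "raw, expected",
        [(0.0, np.log((0.5 / 19) / (1 - 0.5 / 19))), (0.75, np.log((14 / 19) / (5 / 19)))],
    )
    def test_smoothing_formula(self, raw, expected):
        # frozen: logit((raw*18 + 0.5)/19) = -3.611 / 1.030 for raw 0 / 0.75
        got = L.logit_predictability(raw, 18)
        assert got == pytest.approx(expected, abs=1e-12)
        assert {0.0: -3.611, 0.75: 1.030}[raw] == pytest.approx(got, abs=5e-4)

    def test_strictly_increasing_and_finite(self):
        vals = L.logit_predictability(np.linspace(0, 1, 20), 18)
        assert np.all(np.isfinite(vals)) and np.all(np.diff(vals) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            L.logit_predictability(1.5, 18)


class TestTercileSplit:
    def test_one_to_nine(self):
        out = L.tercile_split(np.arange(1, 10))
        assert out.tolist() == ["low"] * 3 + ["mid"] * 3 + ["high"] * 3

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=-1000, max_value=1000),
            min_size=4,
            max_size=40,
            unique=True,
        )
    )
    def test_monotone_transform_invariance(self, values):
        arr = np.array(values, dtype=float)
        base = L.tercile_split(arr)
        # x^3 is strictly monotone and exact in float for |x| <= 1000
        transformed = L.tercile_split(arr**3)
        assert base.tolist() == transformed.tolist()

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            L.tercile_split(np.ones(9))

    def test_tie_block_sizes(self):
        # ties broken by stable input order: group sizes stay balanced
        out = L.tercile_split(np.array([1.0, 1.0, 1.0, 2.0, 2.0, 3.0]))
        sizes = {lab: int((out == lab).sum()) for lab in ("low", "mid", "high")}
        assert sizes == {"low": 2, "mid": 2, "high": 2}
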