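"""Generator contracts: reproducibility, additivity, corpus structure."""

import numpy as np
import pytest

import lmmcbp as L


class TestCorpus:
    def test_bitwise_reproducible(self):
        a = L.simulate_corpus(n_memory=5, n_common=5, seed=42)
        b = L.simulate_corpus(n_memory=5, n_common=5, seed=42)
        assert a.words.equals(b.words)
        assert a.sentences.equals(b.sentences)

    def test_rp_predictability_jump(self):
        c = L.simulate_corpus(seed=1)  # paper-scale defaults: 50 + 80 sentences
        mem = c.words[c.words.sentence_type == "memory_encoded"]
        before = mem[mem.rp_relative_position < 0]["predictability_raw"]
        after = mem[mem.rp_relative_position >= 0]["predictability_raw"]
        assert after.median() > before.median() + 0.3

    def test_rp_is_max_jump(self):
        c = L.simulate_corpus(n_memory=10, n_common=0, seed=3)
        for sid, grp in c.words.groupby("sentence_id"):
            grp = grp.sort_values("position")
            jumps = np.diff(grp["predictability_raw"].to_numpy())
            rp_pos = c.sentences.set_index("sentence_id").loc[sid, "rp_position"]
            assert jumps[int(rp_pos) - 2] == jumps.max()

    def test_no_memory_sentences(self):
        c = L.simulate_corpus(n_memory=0, n_common=5, seed=2)
        assert (c.words.sentence_type == "common").all()
        assert c.words.rp_relative_position.isna().all()

    def test_unique_fraction_without_repetition_tail(self):
        c = L.simulate_corpus(n_memory=4, n_common=4, seed=5, repeated_word_fraction=0.0)
        assert c.unique_word_fraction == 1.0

    def test_mostly_unique_with_tail(self):
        c = L.simulate_corpus(seed=6)  # default 20% repetition tail
        assert 0.5 < c.unique_word_fraction < 1.0

    def test_predictability_finite_logit(self):
        c = L.simulate_corpus(seed=7)
        assert np.isfinite(c.words.predictability).all()
        assert c.words.predictability_raw.between(0, 1).all()


class TestEpochs:
    def test_bitwise_reproducible(self, small_corpus, small_truth, layout8):
        e1, t1 = L.simulate_epochs(small_corpus, small_truth, 3, layout8, seed=9)
        e2, t2 = L.simulate_epochs(small_corpus, small_truth, 3, layout8, seed=9)
        assert np.array_equal(e1.amplitudes, e2.amplitudes)
        assert t1.equals(t2)

    def test_zero_noise_zero_kernels_equals_template(self, small_corpus, layout8):
        truth = L.default_truth(
            layout8, n_times=12, dt_ms=50.0,
            pred_common_amplitude=0.0, position_amplitude=0.0,
            sd_subject=0.0, sd_word=0.0, sd_noise=0.0,
        )
        epochs, _ = L.simulate_epochs(small_corpus, truth, 2, layout8, seed=1)
        for tr in range(epochs.n_trials):
            assert np.array_equal(epochs.amplitudes[tr], truth.intercept)

    def test_generator_additivity(self, small_corpus, layout8):
        def truth_with(pred_amp, pos_amp):
            return L.default_truth(
                layout8, n_times=12, dt_ms=50.0,
                pred_common_amplitude=pred_amp, position_amplitude=pos_amp,
            )

        kw = dict(n_subjects=2, layout=layout8, seed=77)
        both, _ = L.simulate_epochs(small_corpus, truth_with(2.0, 0.5), **kw)
        only_pred, _ = L.simulate_epochs(small_corpus, truth_with(2.0, 0.0), **kw)
        only_pos, _ = L.simulate_epochs(small_corpus, truth_with(0.0, 0.5), **kw)
        neither, _ = L.simulate_epochs(small_corpus, truth_with(0.0, 0.0), **kw)
        lhs = both.amplitudes
        rhs = only_pred.amplitudes + only_pos.amplitudes - neither.amplitudes
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_null_is_zeroed_truth(self, small_corpus, small_truth, layout8):
        null_e, _ = L.simulate_null(small_corpus, small_truth, 2, layout8, seed=4)
        manual_e, _ = L.simulate_epochs(
            small_corpus, small_truth.zeroed(keep_intercept=False), 2, layout8, seed=4
        )
        assert np.array_equal(null_e.amplitudes, manual_e.amplitudes)

    def test_doubling_noise_halves_t(self, small_corpus, layout8):
        spec = L.ModelSpec()
        ts = []
        for sd in (4.0, 8.0):
            truth = L.default_truth(
                layout8, n_times=12, dt_ms=50.0,
                pred_common_amplitude=3.0, sd_subject=0.0, sd_word=0.0, sd_noise=sd,
            )
            epochs, table = L.simulate_epochs(small_corpus, truth, 5, layout8, seed=15)
            epochs, table = L.apply_word_filter(epochs, table)
            stats = L.fit_grid(epochs, table, spec)
            kernel = truth.kernels["predictability:common"]
            region = kernel > 0.5 * kernel.max()  # truth-defined effect region
            ts.append(np.abs(stats.t_map("predictability:common"))[region].mean())
        ratio = ts[0] / ts[1]
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_ground_truth_round_trip(self, small_truth, tmp_path):
        path = tmp_path / "truth.json"
        small_truth.to_json(path)
        back = L.GroundTruth.from_json(path)
        assert np.array_equal(back.intercept, small_truth.intercept)
        assert set(back.kernels) == set(small_truth.kernels)
        for k in back.kernels:
            assert np.array_equal(back.kernels[k], small_truth.kernels[k])

    def test_recovery_of_asymmetric_pred_effect(self, layout8):
        """Nonzero common kernel, zero memory kernel: the fitted estimate
        maps correlate with each injected kernel."""
        corpus = L.simulate_corpus(n_memory=8, n_common=10, seed=21)
        # a > 0.9 map correlation needs slope SE well below the kernel's
        # spread over the grid; within-common logit predictability has a
        # spread of only ~0.5, so SE ~ sd_noise/(0.5*sqrt(n_common)) ~ 0.3
        # against a kernel-value SD of ~0.8 at these settings
        truth = L.default_truth(
            layout8, n_times=12, dt_ms=50.0,
            pred_common_amplitude=6.0, sd_noise=2.5,
        )
        epochs, table = L.simulate_epochs(corpus, truth, 8, layout8, seed=22)
        epochs, table = L.apply_word_filter(epochs, table)
        stats = L.fit_grid(epochs, table, L.ModelSpec())
        common_est = stats.estimates[stats.term_index("predictability:common")]
        kernel = truth.kernels["predictability:common"]
        r = np.corrcoef(common_est.ravel(), kernel.ravel())[0, 1]
        assert r > 0.9
        mem_est = stats.estimates[stats.term_index("predictability:memory_encoded")]
        assert np.abs(mem_est).max() < np.abs(common_est).max()
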