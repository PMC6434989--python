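"""Structure-preserving permutations, null distributions, p-value rules."""

import numpy as np
import pandas as pd
import pytest

import lmmcbp as L
from lmmcbp.clusters import Cluster
from lmmcbp.permutation import NullDistribution, cluster_p_values, make_permutation


def _table(n_subj=4, n_words=6, reps=3):
    rows = []
    tid = 0
    for s in range(n_subj):
        for w in range(n_words):
            for _ in range(reps):
                rows.append({"trial_id": tid, "subject_id": f"S{s}", "word_form": f"w{w}"})
                tid += 1
    return pd.DataFrame(rows)


class TestMakePermutation:
    def test_bijection(self):
        t = _table()
        scheme = L.PermutationScheme("free", 5, seed=1)
        m = make_permutation(t, scheme, 1)
        assert sorted(m.tolist()) == list(range(len(t)))

    @pytest.mark.parametrize(
        "kind,col", [("within_subject", "subject_id"), ("within_word", "word_form")]
    )
    def test_factor_column_preserved_every_iteration(self, kind, col):
        t = _table()
        scheme = L.PermutationScheme(kind, 10, seed=3)
        for it in range(1, 11):
            m = make_permutation(t, scheme, it)
            permuted = t.iloc[m].reset_index(drop=True)
            assert permuted[col].tolist() == t[col].tolist()
            # while the *other* factor does move
            other = "word_form" if col == "subject_id" else "subject_id"
            assert permuted[other].tolist() != t[other].tolist()

    def test_deterministic_in_seed_and_iteration(self):
        t = _table()
        scheme = L.PermutationScheme("within_subject", 5, seed=9)
        a = make_permutation(t, scheme, 2)
        b = make_permutation(t, scheme, 2)
        c = make_permutation(t, scheme, 3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_singleton_level_stays_fixed(self):
        t = pd.DataFrame(
            {
                "trial_id": range(4),
                "subject_id": ["S0"] * 4,
                "word_form": ["solo", "rep", "rep", "rep"],
            }
        )
        scheme = L.PermutationScheme("within_word", 20, seed=5)
        for it in range(1, 21):
            m = make_permutation(t, scheme, it)
            assert m[0] == 0  # the unique word cannot move

    def test_unique_words_make_within_word_identity(self):
        t = pd.DataFrame(
            {"trial_id": range(6), "subject_id": ["S0"] * 6, "word_form": list("abcdef")}
        )
        scheme = L.PermutationScheme("within_word", 3, seed=0)
        for it in range(1, 4):
            assert np.array_equal(make_permutation(t, scheme, it), np.arange(6))
        assert L.effective_shuffling_fraction(t, scheme, n_draws=5) == 0.0


def _null(terms, values):
    arr = np.asarray(values, dtype=float)[None, :]
    return NullDistribution(
        terms=list(terms),
        max_pos=arr,
        max_neg=-arr,
        max_abs=arr,
        scheme=L.PermutationScheme("within_subject", arr.shape[1], seed=0),
        t_th=2.0,
        mappings=np.zeros((arr.shape[1], 1), dtype=int),
    )


def _cluster(mass):
    return Cluster(members=frozenset({(0, 0), (0, 1)}), sign=1 if mass > 0 else -1, mass=mass)


class TestPValueRule:
    def test_zero_exceedances_reports_floor_bound(self):
        null = _null(["pred"], np.linspace(1, 50, 500))
        out = cluster_p_values({"pred": [_cluster(100.0)]}, null)
        assert out["pred"].p_values == [pytest.approx(1 / 500)]
        assert out["pred"].is_bound == [True]
        assert out["pred"].significant(alpha=0.05)

    def test_three_exceed_of_500(self):
        vals = np.concatenate([np.linspace(1, 50, 497), [60.0, 70.0, 80.0]])
        out = cluster_p_values({"pred": [_cluster(55.0)]}, _null(["pred"], vals))
        assert out["pred"].p_values == [pytest.approx(0.006)]
        assert out["pred"].is_bound == [False]

    def test_all_exceed_gives_one(self):
        out = cluster_p_values({"pred": [_cluster(0.5)]}, _null(["pred"], np.full(100, 10.0)))
        assert out["pred"].p_values == [pytest.approx(1.0)]

    def test_add_observed_convention(self):
        out = cluster_p_values(
            {"pred": [_cluster(100.0)]}, _null(["pred"], np.linspace(1, 50, 99)),
            add_observed=True,
        )
        assert out["pred"].p_values == [pytest.approx(1 / 100)]
        assert out["pred"].is_bound == [False]

    def test_term_mismatch_raises(self):
        with pytest.raises(KeyError):
            cluster_p_values({"freq": [_cluster(1.0)]}, _null(["pred"], np.ones(10)))

    def test_p_never_below_floor(self):
        null = _null(["pred"], np.zeros(250))
        out = cluster_p_values({"pred": [_cluster(9.0)]}, null)
        assert out["pred"].p_values[0] >= 1 / 250


class TestNullDistribution:
    def test_bookkeeping_and_worker_invariance(self, small_dataset, adj8):
        epochs, table = small_dataset
        scheme = L.PermutationScheme("within_subject", 4, seed=21)
        kwargs = dict(
            spec=L.ModelSpec(), adjacency=adj8, scheme=scheme,
            terms=["predictability:common"],
        )
        n1 = L.null_distribution(epochs, table, **kwargs, n_jobs=1)
        n2 = L.null_distribution(epochs, table, **kwargs, n_jobs=2)
        assert n1.max_abs.shape == (1, 4)
        assert np.array_equal(n1.max_abs, n2.max_abs)
        assert np.array_equal(n1.max_pos, n2.max_pos)
        assert np.array_equal(n1.mappings, n2.mappings)
        # absolute maxima dominate the one-sided maxima
        assert np.all(n1.max_abs >= n1.max_pos)
        assert np.all(n1.max_abs >= -n1.max_neg)

    def test_degenerate_identity_scheme_reproduces_observed(self, adj8, small_truth, layout8):
        """With all word forms unique, the within-word scheme is the
        identity, so every permutation MaxSum equals the observed one."""
        corpus = L.simulate_corpus(
            n_memory=3, n_common=4, seed=33, repeated_word_fraction=0.0
        )
        epochs, table = L.simulate_epochs(
            corpus, small_truth, n_subjects=1, layout=layout8, seed=34
        )
        # single subject: drop the subject random factor
        spec = L.ModelSpec(random_factors=("word_form",))
        epochs2, table2 = L.apply_word_filter(epochs, table)
        stats = L.fit_grid(epochs2, table2, spec)
        term = "position:common"
        observed = L.find_clusters(stats.t_map(term), adj8, epochs2.electrodes)
        obs_max = L.max_cluster_mass(observed)[2]
        null = L.null_distribution(
            epochs2, table2, spec, adj8,
            L.PermutationScheme("within_word", 3, seed=1), terms=[term],
        )
        assert np.allclose(null.max_abs, obs_max)

    def test_run_lmm_cbp_report_layout(self, small_dataset, adj8):
        epochs, table = small_dataset
        res = L.run_lmm_cbp(
            epochs, table, L.ModelSpec(), adj8, n_permutations=2, seed=5
        )
        assert set(res) == {"stats", "within_subject", "within_word"}
        tab = res["within_subject"].cluster_table(epochs.times, epochs.electrodes)
        assert list(tab.columns)[:5] == ["term", "sign", "mass", "size", "p_value"]
        # any reported p respects the 1/N_P floor
        if len(tab):
            assert (tab.p_value >= 1 / 2 - 1e-12).all()
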