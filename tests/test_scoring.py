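import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

import emtraj as et
from emtraj.markers import DEFAULT_MARKERS, MarkerSet
from emtraj.scoring import _zscore


def _marker_matrix(values, genes, prefix="S"):
    values = np.asarray(values, float)
    return et.ExpressionMatrix(
        values, genes, [f"{prefix}{j}" for j in range(values.shape[1])]
    )


class TestEmtScore:
    def test_constructed_z_scores_give_score_two(self):
        # 2 mes genes at z=+1 / 2 epi genes at z=-1 for the first sample
        genes = ["VIM", "CDH2", "CDH1", "DSP"]
        vals = np.array([
            [2.0, 0.0], [2.0, 0.0],   # mesenchymal high in S0
            [0.0, 2.0], [0.0, 2.0],   # epithelial high in S1
        ])
        score = et.emt_score(_marker_matrix(vals, genes))
        assert score.iloc[0] == pytest.approx(2.0)
        assert score.iloc[1] == pytest.approx(-2.0)

    def test_constant_matrix_scores_zero(self):
        genes = ["VIM", "CDH1"]
        score = et.emt_score(_marker_matrix(np.full((2, 5), 3.0), genes))
        np.testing.assert_allclose(score.to_numpy(), 0.0)

    def test_matches_formula_oracle(self, small_cohort):
        bulk, _ = small_cohort
        score = et.emt_score(bulk)
        df = bulk.to_frame()
        z = df.sub(df.mean(axis=1), axis=0).div(df.std(axis=1, ddof=0), axis=0)
        expected = (
            z.loc[list(DEFAULT_MARKERS.mesenchymal)].mean()
            - z.loc[list(DEFAULT_MARKERS.epithelial)].mean()
        )
        np.testing.assert_allclose(score.to_numpy(), expected.to_numpy(), atol=1e-10)

    def test_affine_invariance_per_gene(self, small_cohort):
        bulk, _ = small_cohort
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 2.0, bulk.n_genes)[:, None]
        b = rng.normal(size=(bulk.n_genes, 1))
        shifted = et.ExpressionMatrix(a * bulk.values + b, bulk.gene_ids,
                                      bulk.sample_ids)
        np.testing.assert_allclose(
            et.emt_score(bulk).to_numpy(), et.emt_score(shifted).to_numpy(),
            atol=1e-9,
        )

    def test_ordering_matches_planted_states(self, small_cohort):
        bulk, truth = small_cohort
        score = et.emt_score(bulk)
        med = {s: score[truth.true_state == s].median() for s in ("EPI", "hEMT", "MES")}
        assert med["EPI"] < med["hEMT"] < med["MES"]

    def test_no_marker_overlap_rejected(self):
        m = _marker_matrix(np.ones((2, 3)), ["X1", "X2"])
        with pytest.raises(ValueError, match="marker"):
            et.emt_score(m)


class TestSelectStateMarkers:
    def test_planted_linear_marker_is_selected(self):
        rng = np.random.default_rng(1)
        n = 300
        t = np.sort(rng.uniform(0, 100, n))
        genes = list(DEFAULT_MARKERS.all_genes)
        vals = rng.normal(size=(len(genes), n))
        vals[genes.index("VIM")] = 0.05 * t + rng.normal(0, 0.1, n)
        expr = _marker_matrix(vals, genes)
        selected = et.select_state_markers(expr, t, seed=0)
        assert "VIM" in selected

    def test_constant_pseudotime_falls_back_to_all_markers(self, small_cohort):
        bulk, _ = small_cohort
        with pytest.warns(UserWarning, match="falling back"):
            selected = et.select_state_markers(bulk, np.zeros(bulk.n_samples))
        assert set(selected) == set(DEFAULT_MARKERS.all_genes)

    def test_collinear_duplicate_at_least_one_selected(self):
        rng = np.random.default_rng(2)
        n = 300
        t = np.sort(rng.uniform(0, 100, n))
        genes = list(DEFAULT_MARKERS.all_genes)
        vals = rng.normal(size=(len(genes), n))
        signal = 0.05 * t + rng.normal(0, 0.1, n)
        vals[genes.index("VIM")] = signal
        vals[genes.index("FN1")] = signal  # exact duplicate of the informative gene
        selected = et.select_state_markers(_marker_matrix(vals, genes), t, seed=0)
        assert {"VIM", "FN1"} & set(selected)

    def test_too_few_samples_rejected(self):
        expr = _marker_matrix(np.ones((32, 5)), list(DEFAULT_MARKERS.all_genes))
        with pytest.raises(ValueError, match="10 samples"):
            et.select_state_markers(expr, np.arange(5))


class TestStateHMM:
    @pytest.fixture(scope="class")
    def planted_chain(self):
        rng = np.random.default_rng(5)
        T = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        z = [0]
        for _ in range(599):
            z.append(rng.choice(3, p=T[z[-1]]))
        z = np.array(z)
        means = np.array([-3.0, 0.0, 3.0])
        vals = means[z][None, :] + rng.normal(0, 0.5, (3, 600))
        expr = _marker_matrix(vals, ["ga", "gb", "gc"])
        return expr, z, T

    def test_single_state_degenerate(self):
        expr = _marker_matrix(np.random.default_rng(0).normal(size=(2, 20)),
                              ["ga", "gb"])
        model, assign = et.fit_state_hmm(expr, np.arange(20), n_states=1, seed=0)
        np.testing.assert_allclose(model.transitions, [[1.0]])
        assert np.all(assign.raw_states == 0)

    def test_three_planted_segments_recovered(self, planted_chain):
        expr, z, T = planted_chain
        model, assign = et.fit_state_hmm(expr, np.arange(600), n_states=3, seed=0)
        conf = np.zeros((3, 3))
        for t_, p_ in zip(z, assign.raw_states):
            conf[t_, p_] += 1
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / 600 >= 0.95

    def test_transitions_estimated_close_to_planted(self, planted_chain):
        expr, z, T = planted_chain
        model, assign = et.fit_state_hmm(expr, np.arange(600), n_states=3, seed=0)
        conf = np.zeros((3, 3))
        for t_, p_ in zip(z, assign.raw_states):
            conf[t_, p_] += 1
        r, c = linear_sum_assignment(-conf)
        order = np.empty(3, int)
        for t_, p_ in zip(r, c):
            order[t_] = p_
        est = model.transitions[np.ix_(order, order)]
        assert np.abs(est - T).max() < 0.05

    def test_posteriors_sum_to_one(self, planted_chain):
        expr, _, _ = planted_chain
        _, assign = et.fit_state_hmm(expr, np.arange(600), n_states=3, seed=0)
        np.testing.assert_allclose(assign.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_same_seed_identical_model(self, planted_chain):
        expr, _, _ = planted_chain
        m1, a1 = et.fit_state_hmm(expr, np.arange(600), n_states=3, seed=4)
        m2, a2 = et.fit_state_hmm(expr, np.arange(600), n_states=3, seed=4)
        np.testing.assert_array_equal(m1.transitions, m2.transitions)
        np.testing.assert_array_equal(m1.emission_means, m2.emission_means)
        np.testing.assert_array_equal(a1.raw_states, a2.raw_states)

    def test_n_states_exceeding_samples_rejected(self):
        expr = _marker_matrix(np.ones((2, 3)), ["ga", "gb"])
        with pytest.raises(ValueError):
            et.fit_state_hmm(expr, np.arange(3), n_states=5)


class TestLabelStates:
    def test_planted_cohort_labels_match_terciles(self, small_cohort):
        bulk, truth = small_cohort
        _, assign = et.segment_cohort(bulk, truth.true_pseudotime, seed=0)
        acc = (assign.labels.to_numpy() == truth.true_state).mean()
        assert acc >= 0.85

    def test_label_invariance_under_state_permutation(self, small_cohort):
        from dataclasses import replace

        bulk, truth = small_cohort
        selected = et.select_state_markers(bulk, truth.true_pseudotime, seed=0)
        sub = bulk.subset_genes(selected)
        model, assign = et.fit_state_hmm(sub, truth.true_pseudotime, seed=0)
        lm1, la1 = et.label_states(model, assign, bulk)
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        permuted_model = replace(
            model,
            emission_means=model.emission_means[inv],
            emission_variances=model.emission_variances[inv],
            transitions=model.transitions[np.ix_(inv, inv)],
            initial_probs=model.initial_probs[inv],
            state_labels=None,
        )
        permuted_assign = replace(
            assign,
            raw_states=perm[assign.raw_states],
            posteriors=assign.posteriors[:, inv],
        )
        lm2, la2 = et.label_states(permuted_model, permuted_assign, bulk)
        pd.testing.assert_series_equal(la1.labels, la2.labels)

    def test_wrong_state_count_rejected(self):
        expr = _marker_matrix(np.random.default_rng(0).normal(size=(2, 30)),
                              ["ga", "gb"])
        model, assign = et.fit_state_hmm(expr, np.arange(30), n_states=2, seed=0)
        with pytest.raises(ValueError, match="3 states"):
            et.label_states(model, assign, expr)


class TestTransitionSummary:
    def test_rows_sum_to_one_and_labelled(self, small_cohort):
        bulk, truth = small_cohort
        model, _ = et.segment_cohort(bulk, truth.true_pseudotime, seed=0)
        trans = et.transition_summary(model)
        assert list(trans.index) == ["EPI", "hEMT", "MES"]
        np.testing.assert_allclose(trans.sum(axis=1).to_numpy(), 1.0, atol=1e-9)

    def test_unlabelled_model_rejected(self):
        expr = _marker_matrix(np.random.default_rng(0).normal(size=(2, 30)),
                              ["ga", "gb"])
        model, _ = et.fit_state_hmm(expr, np.arange(30), n_states=3, seed=0)
        with pytest.raises(ValueError, match="labelled"):
            et.transition_summary(model)


class TestNoiseRobustness:
    def test_zero_noise_keeps_assignment(self, small_cohort):
        bulk, truth = small_cohort
        table = et.evaluate_noise_robustness(
            bulk, truth.true_pseudotime, [0.0], n_reps=1, seed=0
        )
        assert table["accuracy_vs_original"].iloc[0] == 1.0
        assert table["fraction_reassigned"].iloc[0] == 0.0

    def test_saturating_noise_drops_toward_chance(self, small_cohort):
        bulk, truth = small_cohort
        span = bulk.values.max() - bulk.values.min()
        table = et.evaluate_noise_robustness(
            bulk, truth.true_pseudotime, [10 * span], n_reps=2, seed=0
        )
        assert table["accuracy_vs_original"].mean() < 0.7

    def test_empty_grid_rejected(self, small_cohort):
        bulk, truth = small_cohort
        with pytest.raises(ValueError, match="noise_grid"):
            et.evaluate_noise_robustness(bulk, truth.true_pseudotime, [], n_reps=1)


def test_zscore_constant_rows_map_to_zero():
    vals = np.vstack([np.full(4, 2.0), np.arange(4.0)])
    z = _zscore(vals)
    np.testing.assert_allclose(z[0], 0.0)
    assert z[1].mean() == pytest.approx(0.0)


def test_marker_set_disjointness_enforced():
    with pytest.raises(ValueError, match="disjoint"):
        MarkerSet(epithelial=("CDH1",), mesenchymal=("CDH1", "VIM"), hybrid=("PDPN",))
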