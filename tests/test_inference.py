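import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectocca.connectome import EdgeIndex, assign_edge_communities, default_community_table
from connectocca.inference import (
    ModeResult,
    bh_fdr,
    covariate_effects,
    evaluate_modes,
    mode_overlap,
    network_strength,
    permutation_test,
    select_modes,
    sensitivity_compare,
    stable_contributors,
)
from connectocca.rcca import RCCA, tune_lambdas
from connectocca.synthetic import SyntheticSpec, generate_dataset

from conftest import single_mode_blocks, zscore


def brute_force_bh(p):
    """Step-up BH oracle, straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestPermutationTest:
    def test_add_one_formula_floor(self, rng):
        X, Y, *_ = single_mode_blocks(0, n=100, p=10, q=4, rho=0.9)
        pt = permutation_test(X, Y, 0.1, 0.1, n_perms=99, seed=0)
        assert pt.p_values[0] == pytest.approx(1 / 100)
        assert np.all(pt.p_values >= 1 / 100)

    def test_reproducible_under_seed(self, rng):
        X = rng.standard_normal((60, 5))
        Y = rng.standard_normal((60, 3))
        p1 = permutation_test(X, Y, 0.5, 0.5, n_perms=50, seed=9).p_values
        p2 = permutation_test(X, Y, 0.5, 0.5, n_perms=50, seed=9).p_values
        np.testing.assert_array_equal(p1, p2)

    def test_null_calibration_small(self, rng):
        """Short calibration run (40 replicates); the 200-replicate version
        is in the acceptance suite."""
        rej = 0
        for _ in range(40):
            X = rng.standard_normal((100, 4))
            Y = rng.standard_normal((100, 3))
            pt = permutation_test(X, Y, 0.5, 0.5, n_perms=99, seed=rng.integers(2**31))
            rej += pt.p_values[0] <= 0.05
        assert rej / 40 <= 0.15

    def test_zero_perms_rejected(self, rng):
        X = rng.standard_normal((30, 3))
        with pytest.raises(ValueError):
            permutation_test(X, X.copy(), 0.1, 0.1, n_perms=0)


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.30]), [0.03, 0.03, 0.30], atol=1e-12
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03, 0.03, 0.03]), [0.03] * 3)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_matches_brute_force_oracle(self, seed, m):
        p = np.random.default_rng(seed).uniform(1e-9, 1.0, m)
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestSelectModes:
    @pytest.mark.parametrize(
        "q,frac,expected",
        [
            ([0.04], [0.5], [0]),
            ([0.04], [0.03], []),
            ([0.20], [0.5], []),
            ([0.01, 0.04, 0.2], [0.5, 0.2, 0.1], [0, 1]),
        ],
    )
    def test_joint_gate(self, q, frac, expected):
        assert select_modes(q, frac).tolist() == expected


class TestLoadingsAndContributors:
    def test_variable_equal_to_variate_loads_one(self, rng):
        X, Y, *_ = single_mode_blocks(1, n=150, p=5, q=3, rho=0.9)
        res = RCCA(zscore(X), zscore(Y)).fit(0.05, 0.05)
        # append the variate itself as an extra brain column
        X2 = np.column_stack([zscore(X), res.variates_x[:, 0]])
        res2 = RCCA(X2, zscore(Y)).fit(0.05, 0.05)
        brain, _ = res2.loadings()
        assert abs(brain[-1, 0]) > 0.99

    def test_planted_behaviors_load_high_nonplanted_low(self):
        spec = SyntheticSpec(
            n_subjects=1000, n_nodes=20, n_modes=1, canonical_rhos=(0.9,),
            edge_loading_blocks=((("DMN", "DAN"),),),
            behavior_loading_sets=((0, 1, 2, 3),),
            confound_effect_size=0.0, seed=8,
        )
        ds = generate_dataset(spec)
        res = RCCA(zscore(ds.edge_features), zscore(ds.behaviors)).fit(0.2, 0.2)
        _, beh = res.loadings()
        assert np.all(np.abs(beh[:4, 0]) > 0.5)
        assert np.all(np.abs(beh[4:, 0]) < 0.2)

    def test_threshold_rule(self):
        assert stable_contributors([0.5, 0.1], 0.2).tolist() == [0]
        assert stable_contributors([0.5, -0.1], 0.0).size == 2
        with pytest.raises(ValueError):
            stable_contributors([0.5], 1.5)


class TestNetworkStrength:
    @pytest.fixture
    def labeled_index(self):
        comm = default_community_table(14)  # 2 nodes per community
        return assign_edge_communities(EdgeIndex.from_n_nodes(14), comm)

    def test_single_edge_bookkeeping(self, labeled_index):
        loadings = np.zeros(labeled_index.n_edges)
        # edge between node 0 (DMN) and node 6 (DAN)
        e = next(
            i for i in range(labeled_index.n_edges)
            if (labeled_index.node_i[i], labeled_index.node_j[i]) == (0, 6)
        )
        loadings[e] = -0.4
        ns = network_strength(loadings, [e], labeled_index)
        assert ns.pair_strength[("DAN", "DMN")] == pytest.approx(0.4)
        assert ns.node_strength[0] == pytest.approx(0.4)
        assert ns.node_strength[6] == pytest.approx(0.4)

    def test_conservation_sum(self, labeled_index, rng):
        loadings = rng.uniform(-1, 1, labeled_index.n_edges)
        edges = rng.choice(labeled_index.n_edges, 30, replace=False)
        ns = network_strength(loadings, edges, labeled_index)
        assert ns.total_strength == pytest.approx(np.abs(loadings[edges]).sum())

    def test_no_contributing_edges(self, labeled_index):
        ns = network_strength(np.zeros(labeled_index.n_edges), [], labeled_index)
        assert ns.total_strength == 0.0

    def test_unknown_edge_rejected(self, labeled_index):
        with pytest.raises(ValueError):
            network_strength(np.zeros(labeled_index.n_edges), [10**6], labeled_index)


def _mode(edges, loadings, n_edges=20):
    lb = np.zeros(n_edges)
    lb[list(edges)] = loadings
    return ModeResult(
        mode_id=0, observed_correlation=0.5, p_value=0.01, q_value=0.02,
        covariance_fraction=0.2, selected=True, loadings_brain=lb,
        loadings_behavior=np.zeros(3), contributing_edges=np.array(list(edges)),
        contributing_behaviors=np.array([0]),
    )


class TestModeOverlap:
    def test_set_algebra(self):
        a = _mode([1, 2, 3], [0.5, 0.5, 0.5])
        b = _mode([2, 3, 4], [0.4, 0.4, 0.4])
        shared, _ = mode_overlap(a, b)
        assert shared.tolist() == [2, 3]
        shared_same, _ = mode_overlap(a, a)
        assert shared_same.tolist() == [1, 2, 3]
        disjoint, _ = mode_overlap(a, _mode([10, 11], [0.3, 0.3]))
        assert disjoint.size == 0

    def test_mean_strengths_on_shared_edges(self):
        comm = default_community_table(14)
        index = assign_edge_communities(EdgeIndex.from_n_nodes(14), comm)
        a = _mode([0, 1], [0.4, 0.2], n_edges=index.n_edges)
        b = _mode([0, 2], [0.6, 0.8], n_edges=index.n_edges)
        shared, summary = mode_overlap(a, b, index)
        assert shared.tolist() == [0]
        # edge 0 joins nodes 0,1 (both DMN): mean of 0.4 and 0.6
        assert summary.pair_strength[("DMN", "DMN")] == pytest.approx(0.5)


class TestSensitivityCompare:
    def test_identical_fits_r_one(self, rng):
        X, Y, *_ = single_mode_blocks(2, n=120, p=15, q=5, rho=0.85)
        res = RCCA(zscore(X), zscore(Y)).fit(0.2, 0.2)
        out = sensitivity_compare(res, res)
        assert np.allclose(out["r_brain"], 1.0, atol=1e-10)
        assert np.allclose(out["r_behavior"], 1.0, atol=1e-10)

    def test_confound_robustness_on_planted_data(self, random_covariates):
        """With/without confound regression the first-mode loading pattern
        stays nearly identical when confound effects are weak (the study's
        sensitivity analysis)."""
        from connectocca.prep import regress_confounds

        spec = SyntheticSpec(
            n_subjects=300, n_nodes=20, n_modes=1, canonical_rhos=(0.9,),
            edge_loading_blocks=((("DMN", "DAN"),),),
            behavior_loading_sets=((0, 1, 2),),
            confound_effect_size=0.1, seed=10,
        )
        ds = generate_dataset(spec)
        Xr = regress_confounds(ds.edge_features, ds.covariates)
        res_with = RCCA(zscore(Xr), zscore(ds.behaviors)).fit(0.3, 0.3)
        res_without = RCCA(zscore(ds.edge_features), zscore(ds.behaviors)).fit(0.3, 0.3)
        out = sensitivity_compare(res_with, res_without)
        assert out.loc[out["mode_a"] == 0, "r_brain"].iloc[0] > 0.9


class TestCovariateEffects:
    def test_variate_equal_to_age(self, random_covariates):
        cov = random_covariates(200)
        out = covariate_effects(cov["age"].to_numpy(), cov)
        assert out["age_coef"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert out["age_p"].iloc[0] < 1e-10

    def test_antisymmetric_sex_variate(self, random_covariates):
        cov = random_covariates(400)
        c = 0.7
        v = np.where(cov["sex"].to_numpy() == 1, c, -c)
        out = covariate_effects(v, cov)
        assert out["mean_sex1"].iloc[0] - out["mean_sex0"].iloc[0] == pytest.approx(2 * c)

    def test_null_calibration(self, random_covariates):
        ok = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            cov = random_covariates(200, seed=seed)
            out = covariate_effects(r.standard_normal((200, 2)), cov)
            ok += (out["age_q"] > 0.05).all() and (out["sex_q"] > 0.05).all()
        assert ok >= 90

    def test_constant_covariate_dropped_with_warning(self, random_covariates):
        cov = random_covariates(50)
        cov["sex"] = 1.0
        with pytest.warns(UserWarning, match="constant covariate"):
            out = covariate_effects(np.random.default_rng(0).standard_normal(50), cov)
        assert "sex_coef" not in out.columns


class TestEndToEndRecovery:
    def test_two_planted_modes_selected_with_correct_blocks(self):
        """Single-seed version of the 2-mode recovery check (10 seeds in the
        acceptance suite): exactly the two planted modes survive the
        permutation/FDR/covariance gates and each mode's strongest
        community pair is its planted block."""
        spec = SyntheticSpec(n_subjects=400, n_nodes=40, seed=0)
        ds = generate_dataset(spec)
        from connectocca.prep import regress_confounds

        X = zscore(regress_confounds(ds.edge_features, ds.covariates))
        Y = zscore(ds.behaviors)
        tr = tune_lambdas(X, Y, grid_len=10, seed=0)
        res = RCCA(X, Y).fit(*tr.best_pair)
        modes = evaluate_modes(res, edge_index=ds.edge_index, n_perms=499, seed=1)
        chosen = [m for m in modes if m.selected]
        assert [m.mode_id for m in chosen] == [0, 1]
        tops = [
            max(m.network_summary.pair_strength.items(), key=lambda t: t[1])[0]
            for m in chosen
        ]
        assert tops == [("DAN", "DMN"), ("AFN", "VN")]
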