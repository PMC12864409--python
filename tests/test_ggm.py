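import numpy as np
import pandas as pd
import pytest

import panelnet as pn
from panelnet._glasso import constrained_mle
from panelnet.ggm import gaussian_loglik

from _oracles import oracle_glasso


def _random_corr(rng, n, p=4):
    return np.corrcoef(rng.standard_normal((n, p)), rowvar=False)


class TestCorrelationMatrix:
    def test_duplicated_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(100)})
        S = pn.correlation_matrix(df)
        assert S[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((100_000, 5)))
        S = pn.correlation_matrix(df)
        off = S[np.triu_indices(5, 1)]
        assert np.abs(off).max() < 0.02

    def test_pearson_and_spearman_differ_on_skewed_scores(self, study_panel):
        X = study_panel.wave_frame("T0")
        Sp = pn.correlation_matrix(X, method="pearson")
        Ss = pn.correlation_matrix(X, method="spearman")
        for S in (Sp, Ss):
            assert np.linalg.eigvalsh(S).min() >= -1e-10
            assert np.allclose(np.diag(S), 1.0)
        assert not np.allclose(Sp, Ss)

    def test_zero_variance_column_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "flat": [5.0, 5, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            pn.correlation_matrix(df)

    def test_listwise_deletion(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((50, 3)))
        df.iloc[0, 0] = np.nan
        S = pn.correlation_matrix(df)
        expected = np.corrcoef(df.dropna().to_numpy(), rowvar=False)
        assert np.allclose(S, expected)


class TestGlasso:
    def test_unpenalized_matches_matrix_inverse(self):
        S = _random_corr(np.random.default_rng(3), 200, 6)
        assert np.abs(pn.glasso_fit(S, 0.0) - np.linalg.inv(S)).max() < 1e-6

    def test_full_shrinkage_gives_empty_network(self):
        S = _random_corr(np.random.default_rng(4), 100, 5)
        lam = np.abs(S - np.diag(np.diag(S))).max()
        W = pn.precision_to_partial(pn.glasso_fit(S, lam))
        assert np.abs(W).max() == 0.0

    def test_matches_convex_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            S = _random_corr(rng, int(rng.integers(20, 200)))
            lam = rng.uniform(0.02, 0.4)
            assert np.abs(pn.glasso_fit(S, lam) - oracle_glasso(S, lam)).max() <= 1e-4

    def test_matches_sklearn_graphical_lasso(self):
        """Cross-check against an independent implementation of the same
        objective."""
        from sklearn.covariance import graphical_lasso

        rng = np.random.default_rng(6)
        for _ in range(5):
            S = _random_corr(rng, 200, 6)
            lam = rng.uniform(0.05, 0.3)
            _, T_skl = graphical_lasso(S, alpha=lam, tol=1e-10, max_iter=5000)
            assert np.abs(pn.glasso_fit(S, lam) - T_skl).max() < 1e-3

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            pn.glasso_fit(np.eye(3), -0.1)

    def test_constrained_mle_zero_pattern_and_fit(self):
        """Support-constrained MLE: excluded entries exactly zero, support
        entries reproduce S when inverted (the defining moment conditions)."""
        rng = np.random.default_rng(7)
        S = _random_corr(rng, 500, 5)
        support = np.eye(5, dtype=bool)
        support[0, 1] = support[1, 0] = support[2, 3] = support[3, 2] = True
        T = constrained_mle(S, support)
        assert np.all(T[~support & ~np.eye(5, dtype=bool)] == 0)
        W = np.linalg.inv(T)
        assert np.abs(W[support] - S[support]).max() < 1e-6


class TestPrecisionToPartial:
    def test_identity_gives_empty_network(self):
        assert np.abs(pn.precision_to_partial(np.eye(4))).max() == 0.0

    def test_two_by_two_closed_form(self):
        Theta = np.array([[1.0, -0.5], [-0.5, 1.0]])
        W = pn.precision_to_partial(Theta)
        assert W[0, 1] == pytest.approx(0.5)

    def test_matches_inverse_correlation_oracle(self):
        rng = np.random.default_rng(8)
        R = _random_corr(rng, 300, 3)
        Theta = np.linalg.inv(R)
        d = np.sqrt(np.diag(Theta))
        expected = -Theta / np.outer(d, d)
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(pn.precision_to_partial(Theta), expected)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            pn.precision_to_partial(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestEbicScore:
    def test_zero_edges_reduces_to_deviance(self):
        assert pn.ebic_score(-123.0, 50, 0, 10) == pytest.approx(246.0)

    def test_worked_value(self):
        val = pn.ebic_score(-500.0, 100, 5, 10, gamma=0.5)
        assert val == pytest.approx(1000 + 5 * np.log(100) + 10 * np.log(10))
        assert val == pytest.approx(1046.0517, abs=1e-4)

    def test_monotone_in_gamma(self):
        lo = pn.ebic_score(-500.0, 100, 5, 10, gamma=0.25)
        hi = pn.ebic_score(-500.0, 100, 5, 10, gamma=0.5)
        assert hi > lo


class TestEstimateNetwork:
    def test_independent_data_selects_empty_network(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.standard_normal((2000, 10)), columns=pn.NODE_LABELS)
        net = pn.estimate_network(df)
        assert net.edge_count() == 0

    def test_strong_edges_recovered_with_signs(self, latent_truth, latent_network):
        rho = latent_truth.partial_correlations
        est = latent_network.weights
        strong = np.abs(rho) >= 0.3
        assert np.all(np.abs(est[strong]) > 0)
        assert np.all(np.sign(est[strong]) == np.sign(rho[strong]))

    def test_deterministic(self, latent_panel):
        X = latent_panel.wave_frame("T0")
        n1 = pn.estimate_network(X)
        n2 = pn.estimate_network(X)
        assert np.array_equal(n1.weights, n2.weights)
        assert n1.lambda_selected == n2.lambda_selected

    def test_path_edge_count_monotone_in_lambda(self, latent_network, study_panel):
        nets = [latent_network, pn.estimate_network(study_panel.wave_frame("T0"))]
        for net in nets:
            path = sorted(net.path, key=lambda r: r[0])  # ascending lambda
            counts = [r[1] for r in path]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_selected_ebic_is_path_minimum(self, latent_network):
        assert latent_network.ebic_selected == pytest.approx(
            min(r[2] for r in latent_network.path)
        )

    def test_weights_symmetric_zero_diagonal_bounded(self, latent_network):
        W = latent_network.weights
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0)
        assert np.abs(W).max() < 1

    def test_refit_weights_unshrunken_against_penalized(self, latent_panel):
        X = latent_panel.wave_frame("T0")
        refit = pn.estimate_network(X)
        shrunk = pn.estimate_network(X, refit_weights=False)
        strong = np.abs(refit.weights) >= 0.3
        # same support, penalized magnitudes strictly smaller on strong edges
        assert np.array_equal(refit.weights != 0, shrunk.weights != 0)
        assert np.all(np.abs(shrunk.weights[strong]) < np.abs(refit.weights[strong]))

    def test_network_json_round_trip(self, latent_network, tmp_path):
        f = tmp_path / "net.json"
        latent_network.to_json(f)
        back = pn.GGMNetwork.from_json(f)
        assert np.allclose(back.weights, latent_network.weights)
        assert back.path == latent_network.path


class TestRedundancyScreen:
    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(300)
        df = pd.DataFrame(
            {
                "a": x,
                "a_copy": x + rng.normal(0, 0.01, 300),
                "c": rng.standard_normal(300),
                "d": rng.standard_normal(300),
            }
        )
        rep = pn.redundancy_screen(df)
        assert ("a", "a_copy") in rep.flagged_pairs

    def test_independent_columns_produce_no_candidates(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.standard_normal((500, 6)))
        rep = pn.redundancy_screen(df)
        assert rep.candidate_pairs.empty
        assert rep.flagged_pairs == []

    def test_default_fixture_has_no_redundant_nodes(self, study_panel):
        rep = pn.redundancy_screen(study_panel.wave_frame("T0"))
        assert rep.flagged_pairs == []

    def test_proportions_within_unit_interval(self, study_panel):
        rep = pn.redundancy_screen(study_panel.wave_frame("T0"), r_min=0.1)
        prop = rep.candidate_pairs["prop_significant"]
        assert ((prop >= 0) & (prop <= 1)).all()

    def test_too_few_nodes_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((30, 2)))
        with pytest.raises(ValueError, match="3 nodes"):
            pn.redundancy_screen(df)


def test_gaussian_loglik_matches_closed_form():
    rng = np.random.default_rng(12)
    S = _random_corr(rng, 100, 4)
    Theta = np.linalg.inv(S)
    ll = gaussian_loglik(S, Theta, 100)
    assert ll == pytest.approx(50 * (np.linalg.slogdet(Theta)[1] - 4))
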