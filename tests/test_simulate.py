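import numpy as np
import pytest
from hypothesis import given, strategies as st

import panelnet as pn
from panelnet.simulate import MarginalSpec, ordinalize


class TestDefaultTruth:
    def test_precision_matrix_positive_definite(self, default_truth):
        assert np.linalg.eigvalsh(default_truth.Omega).min() > 0

    def test_deterministic_construction(self):
        t1, t2 = pn.make_default_truth(1), pn.make_default_truth(1)
        assert np.array_equal(t1.Omega, t2.Omega)
        assert np.array_equal(t1.Bmat, t2.Bmat)
        assert np.array_equal(t1.noise_sd, t2.noise_sd)

    def test_structure_matches_documented_sparsity(self, default_truth):
        """>=5 strong edges, >=60% structural zeros, AR diagonal in range,
        >=3 cross-lagged effects with at least one negative."""
        rho = default_truth.partial_correlations
        iu = np.triu_indices(10, k=1)
        assert (np.abs(rho[iu]) >= 0.3).sum() >= 5
        assert (np.abs(rho[iu]) < 1e-12).mean() >= 0.6
        # the craving pair is one of the strong edges
        assert abs(rho[0, 1]) >= 0.3
        diag = np.diag(default_truth.Bmat)
        assert np.all((diag >= 0.2) & (diag <= 0.6))
        off = default_truth.Bmat[~np.eye(10, dtype=bool)]
        big = off[np.abs(off) >= 0.15]
        assert len(big) >= 3 and (big < 0).any()

    def test_partial_correlation_from_inverted_omega(self, default_truth):
        """Implied partial correlations agree with direct matrix inversion of
        the correlation matrix (independent route)."""
        Sigma = np.linalg.inv(default_truth.Omega)
        d = np.sqrt(np.diag(Sigma))
        R = Sigma / np.outer(d, d)
        K = np.linalg.inv(R)
        dk = np.sqrt(np.diag(K))
        expected = -K / np.outer(dk, dk)
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(default_truth.partial_correlations, expected, atol=1e-10)


class TestSimulatePanel:
    def test_seed_determinism(self, default_truth):
        p1 = pn.simulate_panel(default_truth)
        p2 = pn.simulate_panel(default_truth)
        assert np.array_equal(p1.scores, p2.scores, equal_nan=True)
        assert np.array_equal(p1.observed, p2.observed)

    def test_attrition_count_matches_design(self, study_panel):
        assert study_panel.n_subjects == 361
        assert study_panel.observed[:, 1].sum() == 209

    def test_waves_independent_when_no_lagged_effects(self):
        truth = pn.make_default_truth(
            9, n0=100_000, marginals=pn.identity_marginals(), noise_sd=1.0
        )
        truth.Bmat = np.zeros((10, 10))
        panel = pn.simulate_panel(truth)
        x0, x1 = panel.completers()
        C = np.corrcoef(x0.to_numpy(), x1.to_numpy(), rowvar=False)[:10, 10:]
        assert np.abs(C).max() < 0.02

    def test_recovery_closure_partial_correlations(self):
        """Empirical partial correlations at n=50k converge to the truth."""
        truth = pn.make_default_truth(4, n0=50_000, marginals=pn.identity_marginals())
        panel = pn.simulate_panel(truth)
        R = np.corrcoef(panel.wave_frame("T0").to_numpy(), rowvar=False)
        K = np.linalg.inv(R)
        d = np.sqrt(np.diag(K))
        pcor = -K / np.outer(d, d)
        np.fill_diagonal(pcor, 0.0)
        assert np.abs(pcor - truth.partial_correlations).max() <= 0.02

    def test_recovery_closure_lagged_coefficients(self):
        """Node-wise OLS on standardized completer data at n=50k recovers the
        standardized lagged matrix."""
        truth = pn.make_default_truth(4, n0=50_000, marginals=pn.identity_marginals())
        panel = pn.simulate_panel(truth)
        x0, x1 = panel.completers()
        Z0 = (x0 - x0.mean()) / x0.std(ddof=0)
        Z1 = (x1 - x1.mean()) / x1.std(ddof=0)
        B_hat, *_ = np.linalg.lstsq(Z0.to_numpy(), Z1.to_numpy(), rcond=None)
        assert np.abs(B_hat - truth.standardized_lagged_matrix()).max() <= 0.02

    def test_attrition_is_mcar(self):
        """Mean baseline score of retained vs dropped differs by < 3 SE."""
        truth = pn.make_default_truth(5, n0=10_000, marginals=pn.identity_marginals())
        panel = pn.simulate_panel(truth)
        kept = panel.observed[:, 1]
        for j in range(10):
            x = panel.scores[:, j, 0]
            a, b = x[kept], x[~kept]
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            assert abs(a.mean() - b.mean()) < 3 * se

    def test_score_dependent_dropout_shifts_retained_mean(self):
        truth = pn.make_default_truth(5, n0=10_000, marginals=pn.identity_marginals())
        panel = pn.simulate_panel(truth, dropout="score_dependent")
        kept = panel.observed[:, 1]
        x = panel.scores[:, 0, 0]  # D1 drives dropout
        assert x[kept].mean() < x[~kept].mean()

    def test_non_positive_definite_omega_rejected(self, default_truth):
        bad = pn.SimulationTruth(
            node_labels=default_truth.node_labels,
            Omega=np.ones((10, 10)),
            Bmat=default_truth.Bmat,
            noise_sd=default_truth.noise_sd,
            marginals=default_truth.marginals,
        )
        with pytest.raises(ValueError, match="eigenvalue"):
            pn.simulate_panel(bad)

    def test_invalid_retention_rejected(self, default_truth):
        with pytest.raises(ValueError, match="retention"):
            pn.make_default_truth(1, retention=0.0)

    def test_scores_respect_instrument_ranges(self, study_panel, default_truth):
        for j, lbl in enumerate(study_panel.node_labels):
            spec = default_truth.marginals[lbl]
            x = study_panel.scores[:, j, :]
            x = x[~np.isnan(x)]
            if spec.kind == "likert":
                assert x.min() >= spec.low and x.max() <= spec.high
                assert np.allclose(x, np.round(x))
            else:
                assert x.min() > 0  # reaction times are positive

    def test_truth_json_round_trip(self, default_truth, tmp_path):
        f = tmp_path / "truth.json"
        default_truth.to_json(f)
        back = pn.SimulationTruth.from_json(f)
        assert np.array_equal(back.Omega, default_truth.Omega)
        assert np.array_equal(back.Bmat, default_truth.Bmat)
        assert back.marginals == default_truth.marginals


class TestOrdinalize:
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=50))
    def test_monotone(self, values):
        spec = MarginalSpec("likert", low=13, high=91, skew=2.0, integer=False)
        z = np.sort(np.asarray(values))
        y = ordinalize(z, spec)
        assert np.all(np.diff(y) >= 0)

    def test_range_clamp(self):
        spec = MarginalSpec("likert", low=13, high=91, skew=1.5, integer=True)
        z = np.random.default_rng(0).standard_normal(5000)
        y = ordinalize(z, spec)
        assert y.min() >= 13 and y.max() <= 91

    def test_constant_input_constant_output(self):
        spec = MarginalSpec("likert", low=4, high=28, skew=2.0, integer=True)
        y = ordinalize(np.zeros(7), spec)
        assert len(np.unique(y)) == 1

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="low < high"):
            MarginalSpec("likert", low=5, high=5)
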