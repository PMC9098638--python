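"""Path construction, glasso contract, EBIC arithmetic, model selection."""

import numpy as np
import pytest
from sklearn.covariance import graphical_lasso as sk_glasso

from ordnet import (GaussianGraphicalModel, GlassoConfig, NetworkModel, ebic,
                    glasso_fit, lambda_path, precision_to_partial_corr,
                    select_network)
from ordnet.simulate import latent_correlation
from tests.conftest import sample_single


def random_corr(p, n, seed):
    rng = np.random.default_rng(seed)
    return np.corrcoef(rng.normal(size=(n, p)).T)


@pytest.fixture(scope="module")
def corr8():
    return random_corr(8, 400, seed=0)


class TestLambdaPath:
    def test_log_spaced_between_max_and_ratio(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.8
        R[1, 2] = R[2, 1] = 0.2
        lams = lambda_path(R, GlassoConfig(n_lambda=100, lambda_min_ratio=0.01))
        assert len(lams) == 100
        assert lams[0] == pytest.approx(0.8)
        assert lams[-1] == pytest.approx(0.008)
        ratios = lams[1:] / lams[:-1]
        assert np.allclose(ratios, ratios[0])
        assert np.all(np.diff(lams) < 0)

    def test_two_lambdas_are_exact_endpoints(self, corr8):
        lmax = np.abs(corr8 - np.eye(8)).max()
        lams = lambda_path(corr8, GlassoConfig(n_lambda=2, lambda_min_ratio=0.01))
        assert lams == pytest.approx([lmax, 0.01 * lmax])

    def test_identity_degenerates_to_empty_network(self):
        lams = lambda_path(np.eye(4))
        assert lams.tolist() == [0.0]
        net, path = select_network(np.eye(4), n=100)
        assert net.edge_count == 0
        assert path.edge_counts.tolist() == [0]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GlassoConfig(n_lambda=1)
        with pytest.raises(ValueError):
            GlassoConfig(lambda_min_ratio=1.5)
        with pytest.raises(ValueError):
            GlassoConfig(gamma=-0.1)


class TestGlassoFit:
    def test_full_shrinkage_at_lambda_max(self, corr8):
        lmax = np.abs(corr8 - np.eye(8)).max()
        theta = glasso_fit(corr8, lmax)
        assert np.allclose(theta - np.diag(np.diag(theta)), 0.0)

    def test_unpenalized_fit_equals_inverse(self, corr8):
        theta = glasso_fit(corr8, 0.0, GlassoConfig(tol=1e-8, max_iter=500))
        assert np.abs(theta - np.linalg.inv(corr8)).max() < 1e-4

    @pytest.mark.parametrize("lam", [0.02, 0.05, 0.1])
    def test_matches_sklearn_solver(self, corr8, lam):
        """Independent oracle: sklearn's graphical_lasso, same objective."""
        theta = glasso_fit(corr8, lam, GlassoConfig(tol=1e-7, max_iter=500))
        _, prec = sk_glasso(corr8, lam, tol=1e-8, max_iter=500)
        assert np.abs(theta - prec).max() < 1e-3
        iu = np.triu_indices(8, 1)
        assert ((np.abs(theta[iu]) > 1e-8)
                == (np.abs(prec[iu]) > 1e-8)).all()

    def test_indirect_edge_shrunk_before_chain_edges(self):
        # 3-node chain latent correlation: the 1-3 link is indirect only
        theta_true = np.array([[1.0, -0.5, 0.0], [-0.5, 1.0, -0.5],
                               [0.0, -0.5, 1.0]])
        R = latent_correlation(theta_true)
        theta = glasso_fit(R, 0.05)
        pcor = precision_to_partial_corr(theta)
        assert abs(pcor[0, 2]) < abs(pcor[0, 1])
        assert abs(pcor[0, 2]) < abs(pcor[1, 2])

    def test_negative_lambda_rejected(self, corr8):
        with pytest.raises(ValueError):
            glasso_fit(corr8, -0.1)


class TestEbic:
    def numpy_ebic(self, theta, S, n, gamma):
        """Independent re-statement of the criterion in plain numpy."""
        E = (np.abs(theta[np.triu_indices(theta.shape[0], 1)]) > 1e-8).sum()
        ll = np.linalg.slogdet(theta)[1] - np.trace(S @ theta)
        return -n * ll + E * np.log(n) + 4 * E * gamma * np.log(theta.shape[0])

    def test_empty_graph_reduces_to_likelihood_term(self, corr8):
        theta = np.diag(1.0 / np.diag(corr8))
        ll = np.linalg.slogdet(theta)[1] - np.trace(corr8 @ theta)
        assert ebic(theta, corr8, n=500, gamma=0.5) == pytest.approx(-500 * ll)

    def test_gamma_zero_is_bic_on_edges(self, corr8):
        theta = np.linalg.inv(corr8)
        E = (np.abs(theta[np.triu_indices(8, 1)]) > 1e-8).sum()
        ll = np.linalg.slogdet(theta)[1] - np.trace(corr8 @ theta)
        assert ebic(theta, corr8, n=500, gamma=0.0) == pytest.approx(
            -500 * ll + E * np.log(500))

    def test_matches_independent_formula(self, corr8):
        theta = glasso_fit(corr8, 0.05)
        for n, gamma in [(500, 0.5), (2000, 0.25)]:
            assert ebic(theta, corr8, n, gamma) == pytest.approx(
                self.numpy_ebic(theta, corr8, n, gamma))

    def test_edge_penalty_difference_hand_value(self):
        """Two more edges at equal likelihood cost 2 log n + 4 gamma 2 log p."""
        n, p, gamma = 500, 8, 0.5
        base = np.eye(p) * 2.0
        t3 = base.copy()
        for i, j in [(0, 1), (2, 3), (4, 5)]:
            t3[i, j] = t3[j, i] = 0.1
        t5 = base.copy()
        for i, j in [(0, 1), (2, 3), (4, 5), (6, 7), (0, 2)]:
            t5[i, j] = t5[j, i] = 0.1
        S = np.eye(p)
        ll3 = np.linalg.slogdet(t3)[1] - np.trace(S @ t3)
        ll5 = np.linalg.slogdet(t5)[1] - np.trace(S @ t5)
        delta = (ebic(t5, S, n, gamma) - ebic(t3, S, n, gamma)
                 + n * (ll5 - ll3))  # remove the likelihood part
        assert delta == pytest.approx(2 * np.log(500) + 4 * np.log(8))

    def test_non_pd_precision_rejected(self, corr8):
        indefinite = np.diag([1.0] * 7 + [-1.0])
        with pytest.raises(ValueError, match="positive definite"):
            ebic(indefinite, corr8, n=100)


class TestSelectNetwork:
    def test_partial_correlation_conversion(self):
        theta = np.array([[2.0, -1.0], [-1.0, 2.0]])
        pcor = precision_to_partial_corr(theta)
        assert pcor[0, 1] == pytest.approx(0.5)
        assert pcor[0, 0] == 0.0

    def test_scale_invariance_of_partial_correlations(self, corr8):
        theta = np.linalg.inv(corr8)
        D = np.diag(np.random.default_rng(1).uniform(0.5, 3.0, 8))
        assert np.allclose(precision_to_partial_corr(theta),
                           precision_to_partial_corr(D @ theta @ D))

    def test_path_invariants_and_selection(self, chain_dataset):
        res = GaussianGraphicalModel(chain_dataset).fit()
        path = res.path
        assert path.edge_counts[0] == 0                      # lambda_max entry
        usable = np.isfinite(path.ebics)
        assert path.ebics[path.selected] == path.ebics[usable].min()
        assert path.edge_counts[0] <= path.edge_counts[-1]

    def test_ties_break_toward_sparser_model(self):
        # weak correlations at tiny n: every usable entry selects 0 edges,
        # EBIC is then constant and the largest lambda must win
        R = np.eye(4)
        for i in range(3):
            R[i, i + 1] = R[i + 1, i] = 0.05
        net, path = select_network(R, n=30)
        assert net.edge_count == 0
        assert path.selected == 0

    def test_null_model_selects_empty_network(self):
        hits = 0
        for s in range(10):
            ds = sample_single(np.eye(8), n=2000, seed=200 + s)
            net, _ = select_network(
                np.asarray(__import__("ordnet").polychoric_matrix(ds).values),
                n=2000)
            hits += net.edge_count == 0
        assert hits >= 9

    def test_unpenalized_weights_match_inverse_formula(self, corr8):
        theta = glasso_fit(corr8, 0.0, GlassoConfig(tol=1e-8, max_iter=500))
        direct = precision_to_partial_corr(np.linalg.inv(corr8))
        assert np.abs(precision_to_partial_corr(theta) - direct).max() < 1e-4


class TestNetworkModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            NetworkModel(["a", "b"], np.array([[0.0, 0.3], [0.1, 0.0]]))
        net = NetworkModel(["a", "b", "c"],
                           np.array([[0.5, 0.2, 0.0], [0.2, 0.0, -0.1],
                                     [0.0, -0.1, 0.3]]))
        assert np.all(np.diag(net.weights) == 0.0)  # diagonal forced to zero
        assert net.edge_count == 2

    def test_edge_list_round_trip(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        net = NetworkModel(["x", "y", "z"], w)
        edges = net.edges()
        assert edges.to_dict("records") == [
            {"node_i": "x", "node_j": "y", "weight": 0.4}]
        assert len(net.edges(include_zero=True)) == 3
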