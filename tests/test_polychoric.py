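"""Polychoric estimation tests: thresholds, pair ML, matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri
from scipy.stats import multivariate_normal

from ordnet import estimate_polychoric_pair, estimate_thresholds, polychoric_matrix
from ordnet._bvn import bvn_cdf
from ordnet.datasets import DegenerateVariableError
from ordnet.polychoric import _nearest_psd_correlation
from ordnet.simulate import latent_correlation
from tests.conftest import sample_single


def column_from_counts(counts):
    return np.repeat(np.arange(len(counts)), counts)


class TestBvnCdf:
    @pytest.mark.parametrize("r", [-0.999, -0.9, -0.5, 0.0, 0.3, 0.8, 0.95, 0.999])
    def test_matches_scipy(self, r):
        for x in (-2.5, -0.7, 0.0, 0.9, 2.1):
            for y in (-1.8, 0.0, 0.4, 2.6):
                ref = multivariate_normal.cdf([x, y], mean=[0, 0],
                                              cov=[[1, r], [r, 1]],
                                              abseps=1e-12, releps=1e-12)
                assert bvn_cdf(x, y, r) == pytest.approx(ref, abs=1e-10)

    def test_infinite_margins(self):
        assert bvn_cdf(np.inf, 0.3, 0.5) == pytest.approx(
            multivariate_normal.cdf(0.3, mean=0, cov=1))
        assert bvn_cdf(-np.inf, 0.3, 0.5) == 0.0
        assert bvn_cdf(np.inf, np.inf, -0.2) == 1.0


class TestThresholds:
    def test_even_binary_split_gives_zero(self):
        thr, cats = estimate_thresholds(column_from_counts([10, 10]))
        assert thr == pytest.approx([0.0])
        assert list(cats) == [0, 1]

    def test_symmetric_proportions_give_symmetric_pair(self):
        thr, _ = estimate_thresholds(column_from_counts([25, 50, 25]))
        assert thr[0] == pytest.approx(-thr[1])
        assert thr[0] == pytest.approx(ndtri(0.25))

    def test_cumulative_quantile_oracle(self):
        thr, _ = estimate_thresholds(column_from_counts([10, 20, 30, 40]))
        assert thr == pytest.approx(ndtri([0.1, 0.3, 0.6]))

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateVariableError, match="degenerate"):
            estimate_thresholds(np.full(50, 3))

    def test_unseen_categories_simply_absent(self):
        # scores on 0-100 grid with a gap: only observed categories matter
        thr, cats = estimate_thresholds(np.array([0, 0, 50, 100, 100]))
        assert list(cats) == [0, 50, 100]
        assert len(thr) == 2


def crosstab(ds):
    v = ds.values.to_numpy()
    k0, k1 = v[:, 0].max() + 1, v[:, 1].max() + 1
    tab = np.zeros((k0, k1))
    for a, b in v:
        tab[a, b] += 1
    return tab


def pair_from_latent(rho, n, seed, n_categories=5):
    """Simulate one latent-rho ordinal pair; return (table, thresholds)."""
    theta = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))
    ds = sample_single(theta, n=n, seed=seed, n_categories=n_categories)
    tab = crosstab(ds)
    tx, _ = estimate_thresholds(ds.values.iloc[:, 0])
    ty, _ = estimate_thresholds(ds.values.iloc[:, 1])
    return tab, tx, ty


class TestPairEstimate:
    def pair_from_latent(self, rho, n, seed, n_categories=5):
        return pair_from_latent(rho, n, seed, n_categories)

    def test_independent_pair_near_zero(self):
        tab, tx, ty = self.pair_from_latent(0.0, 5000, seed=1)
        est = estimate_polychoric_pair(tab, tx, ty)
        assert abs(est.rho) < 0.05
        assert not est.at_boundary

    def test_perfect_concordance_clamped_and_flagged(self):
        tab = np.array([[40.0, 0.0], [0.0, 60.0]])
        est = estimate_polychoric_pair(tab, np.array([0.2]), np.array([0.2]))
        assert est.rho == pytest.approx(1 - 1e-4)
        assert est.at_boundary

    def test_exchangeability(self):
        tab, tx, ty = self.pair_from_latent(0.5, 1500, seed=2)
        a = estimate_polychoric_pair(tab, tx, ty)
        b = estimate_polychoric_pair(tab.T, ty, tx)
        assert a.rho == pytest.approx(b.rho, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            estimate_polychoric_pair(np.ones((3, 3)), np.array([0.0]),
                                     np.array([-1.0, 1.0]))

    def test_recovery_of_moderate_rho(self):
        errs = [estimate_polychoric_pair(
            *self.pair_from_latent(0.5, 2000, seed=s)).rho - 0.5
            for s in range(8)]
        assert abs(np.mean(errs)) < 0.05

    def test_consistency_error_shrinks_with_n(self):
        """Median absolute error decreases over n = 500, 2000, 8000."""
        med = []
        for n in (500, 2000, 8000):
            errs = [abs(estimate_polychoric_pair(
                *self.pair_from_latent(0.5, n, seed=100 + s)).rho - 0.5)
                for s in range(9)]
            med.append(np.median(errs))
        assert med[0] > med[1] > med[2]


class TestPolychoricMatrix:
    def test_identity_latent_near_identity(self):
        n = 4000
        ds = sample_single(np.eye(5), n=n, seed=6)
        R = polychoric_matrix(ds)
        off = R.values[np.triu_indices(5, 1)]
        assert np.abs(off).max() < 3.0 / np.sqrt(n)
        assert np.allclose(np.diag(R.values), 1.0)

    def test_chain_recovers_latent_correlations(self, chain_theta8):
        ds = sample_single(chain_theta8, n=5000, seed=13)
        R = polychoric_matrix(ds)
        target = latent_correlation(chain_theta8)
        assert np.abs(R.values - target).max() < 0.05

    def test_two_variable_case_matches_pair_estimate(self):
        theta = np.linalg.inv(np.array([[1.0, 0.4], [0.4, 1.0]]))
        ds = sample_single(theta, n=1200, seed=8)
        R = polychoric_matrix(ds)
        tab = crosstab(ds)
        tx, _ = estimate_thresholds(ds.values.iloc[:, 0])
        ty, _ = estimate_thresholds(ds.values.iloc[:, 1])
        pair = estimate_polychoric_pair(tab, tx, ty)
        assert R.values[0, 1] == pytest.approx(pair.rho, abs=1e-6)

    def test_degenerate_column_rejected_with_location(self):
        df = pd.DataFrame({"A": [1, 2, 1, 2], "B": [3, 3, 3, 3],
                           "C": [0, 1, 0, 1]})
        with pytest.raises(DegenerateVariableError, match=r"\[1\]"):
            polychoric_matrix(df)

    def test_many_category_limit_approaches_pearson(self):
        theta = np.linalg.inv(np.array([[1.0, 0.6], [0.6, 1.0]]))
        ds = sample_single(theta, n=6000, seed=9, n_categories=15)
        R = polychoric_matrix(ds, max_categories=15)
        pearson = np.corrcoef(ds.values.to_numpy().T)[0, 1]
        assert R.values[0, 1] == pytest.approx(pearson, abs=0.03)
        assert not R.fallback_columns

    def test_high_cardinality_fallback_recorded(self):
        rng = np.random.default_rng(0)
        Z = rng.multivariate_normal([0, 0, 0], latent_correlation(
            np.linalg.inv(np.eye(3) + 0.3 - 0.3 * np.eye(3))), size=800)
        df = pd.DataFrame({
            "ord1": np.digitize(Z[:, 0], [-0.5, 0.5]),
            "ord2": np.digitize(Z[:, 1], [-0.5, 0.5]),
            "cont": np.round(Z[:, 2], 2)})  # hundreds of distinct values
        R = polychoric_matrix(df)
        assert R.fallback_columns == ["cont"]
        pearson = np.corrcoef(df["cont"], df["ord1"])[0, 1]
        assert R.values[0, 2] == pytest.approx(pearson, abs=1e-12)

    def test_psd_repair_clips_and_rescales(self):
        bad = np.array([[1.0, 0.95, -0.9], [0.95, 1.0, 0.8], [-0.9, 0.8, 1.0]])
        assert np.linalg.eigvalsh(bad).min() < 0
        fixed = _nearest_psd_correlation(bad)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-12
        assert np.allclose(np.diag(fixed), 1.0)
        assert np.allclose(fixed, fixed.T)
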