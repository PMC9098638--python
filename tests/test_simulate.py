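"""Generator tests: precision construction, discretized sampling, determinism."""

import numpy as np
import pytest

from ordnet import (DiscretizationSpec, EdgeChange, GroupDesign,
                    TruePrecisionSpec, build_precision, percent_mapping,
                    precision_to_partial_corr, sample_ordinal)
from ordnet.simulate import apply_perturbation, latent_correlation
from tests.conftest import sample_single


def names(p):
    return [f"V{i+1}" for i in range(p)]


class TestBuildPrecision:
    def test_no_edges_gives_identity(self):
        theta = build_precision(TruePrecisionSpec(
            node_names=names(5), structure="random-sparse",
            partial_cor_value=0.4, edge_density=0.0))
        assert np.array_equal(theta, np.eye(5))
        assert np.array_equal(precision_to_partial_corr(theta), np.zeros((5, 5)))

    def test_chain3_partial_correlations(self):
        """Oracle: invert and apply the partial-correlation formula."""
        theta = build_precision(TruePrecisionSpec(
            node_names=names(3), structure="chain", partial_cor_value=0.5))
        sigma = np.linalg.inv(theta)
        prec = np.linalg.inv(sigma)  # round-trip for the oracle
        d = np.sqrt(np.diag(prec))
        pcor = -prec / np.outer(d, d)
        assert pcor[0, 1] == pytest.approx(0.5, abs=1e-6)
        assert pcor[1, 2] == pytest.approx(0.5, abs=1e-6)
        assert abs(pcor[0, 2]) < 1e-10

    @pytest.mark.parametrize("structure,value", [
        ("chain", 0.3), ("chain", -0.4), ("hub", 0.3), ("hub", -0.25)])
    def test_structures_hit_target_and_are_pd(self, structure, value):
        theta = build_precision(TruePrecisionSpec(
            node_names=names(8), structure=structure, partial_cor_value=value))
        assert np.linalg.eigvalsh(theta).min() > 0
        pcor = precision_to_partial_corr(theta)
        edges = np.abs(pcor) > 1e-9
        assert np.allclose(pcor[edges], value, atol=1e-6)

    def test_random_sparse_density(self):
        rng = np.random.default_rng(7)
        theta = build_precision(TruePrecisionSpec(
            node_names=names(8), structure="random-sparse",
            partial_cor_value=0.2, edge_density=0.3), rng=rng)
        assert np.linalg.eigvalsh(theta).min() > 0
        iu = np.triu_indices(8, 1)
        n_edges = int((np.abs(theta[iu]) > 1e-9).sum())
        assert 2 <= n_edges <= 16  # binomial(28, 0.3) central range

    def test_explicit_non_pd_rejected_naming_eigenvalue(self):
        M = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
        assert np.linalg.eigvalsh(M).min() < 0
        with pytest.raises(ValueError, match="smallest eigenvalue"):
            build_precision(TruePrecisionSpec(
                node_names=names(3), structure="explicit", explicit_matrix=M))

    def test_infeasible_target_raises(self):
        # a hub with 7 spokes cannot carry uniform partial correlation 0.6
        with pytest.raises(ValueError, match="infeasible"):
            build_precision(TruePrecisionSpec(
                node_names=names(8), structure="hub", partial_cor_value=0.6))


class TestDiscretizationSpec:
    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            DiscretizationSpec(n_categories=3, thresholds=[np.array([0.5, 0.1])])
        with pytest.raises(ValueError, match="n_categories - 1"):
            DiscretizationSpec(n_categories=4, thresholds=[np.array([0.0])])

    def test_equiprobable_default_cuts(self):
        cuts = DiscretizationSpec(n_categories=4).cut_points(2)
        from scipy.special import ndtri
        assert np.allclose(cuts[0], ndtri([0.25, 0.5, 0.75]))
        assert len(cuts) == 2

    def test_percent_mapping_grid(self):
        ds = sample_ordinal(np.eye(3), DiscretizationSpec(
            n_categories=5, score_mapping=percent_mapping(5)),
            GroupDesign.single(200), seed=0)
        assert set(np.unique(ds.values)) <= {0.0, 25.0, 50.0, 75.0, 100.0}


class TestSampleOrdinal:
    def test_uniform_marginals_under_independence(self):
        ds = sample_single(np.eye(4), n=10000, seed=11)
        for col in ds.node_names:
            freq = ds.values[col].value_counts(normalize=True)
            assert np.allclose(freq.sort_index(), 0.2, atol=0.02)

    def test_strong_association_concentrates_diagonal(self):
        theta = np.array([[1.0, -0.9], [-0.9, 1.0]])
        ds = sample_single(theta, n=4000, seed=3, n_categories=2)
        tab = np.zeros((2, 2))
        v = ds.values.to_numpy()
        for a, b in v:
            tab[a, b] += 1
        assert (tab[0, 0] + tab[1, 1]) / tab.sum() > 0.8

    def test_latent_roundtrip(self, chain_theta8):
        """Latent Pearson correlations converge to the specified matrix."""
        n = 20000
        ds, Z = sample_ordinal(chain_theta8, DiscretizationSpec(),
                               GroupDesign.single(n), seed=5,
                               return_latent=True)
        R_target = latent_correlation(chain_theta8)
        R_emp = np.corrcoef(Z.T)
        assert np.abs(R_emp - R_target).max() < 3.0 / np.sqrt(n)

    def test_seeded_determinism_byte_for_byte(self, chain_theta8, tmp_path):
        design = GroupDesign(group_names=["A", "B"], group_sizes=[50, 40])
        for i in (1, 2):
            ds = sample_ordinal(chain_theta8, DiscretizationSpec(), design, seed=9)
            ds.to_csv(tmp_path / f"run{i}.csv")
        assert (tmp_path / "run1.csv").read_bytes() == \
               (tmp_path / "run2.csv").read_bytes()

    def test_adding_group_preserves_earlier_draws(self, chain_theta8):
        one = sample_ordinal(chain_theta8, DiscretizationSpec(),
                             GroupDesign(["A"], [60]), seed=2)
        two = sample_ordinal(chain_theta8, DiscretizationSpec(),
                             GroupDesign(["A", "B"], [60, 30]), seed=2)
        assert one.values.equals(two.subset("A").values)

    def test_empty_perturbation_reproduces_base_group(self, chain_theta8):
        base = sample_ordinal(chain_theta8, DiscretizationSpec(),
                              GroupDesign(["A", "B"], [50, 50]), seed=4)
        pert = sample_ordinal(chain_theta8, DiscretizationSpec(),
                              GroupDesign(["A", "B"], [50, 50],
                                          perturbations={"B": []}), seed=4)
        assert base.to_frame().equals(pert.to_frame())

    def test_non_pd_perturbation_rejected(self, chain_theta8, chain_names8):
        changes = [EdgeChange("SEL", "AUT", pcor=0.99)]
        with pytest.raises(ValueError, match="positive definite"):
            apply_perturbation(chain_theta8, changes, chain_names8)

    def test_perturbation_sets_target_pcor(self, chain_theta8, chain_names8):
        theta2 = apply_perturbation(
            chain_theta8, [EdgeChange("SEL", "ROM", pcor=0.45)], chain_names8)
        pcor = precision_to_partial_corr(theta2)
        assert pcor[0, 1] == pytest.approx(0.45, abs=1e-12)


class TestGroupDesign:
    def test_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            GroupDesign(["A"], [1])
        with pytest.raises(ValueError, match="unknown group"):
            GroupDesign(["A"], [10], perturbations={"Z": []})
        with pytest.raises(ValueError, match="length"):
            GroupDesign(["A", "B"], [10])
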