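"""Phylogenetic machinery: BM covariance, Pagel's lambda, lambda-PGLS."""


import dendropy
import numpy as np
import pytest
from dendropy.model import continuous
from scipy import stats

import limbscale as ls
from limbscale.phylo import (
    Phylogeny,
    _gls_profile_loglik,
    bm_covariance,
    fit_lambda_ml,
    lambda_transform,
    normalize_name,
    pgls_lambda_regression,
    read_newick,
    residual_signal_test,
    set_branch_lengths_unity,
    write_newick,
)


def _tree_from_string(newick):
    t = dendropy.Tree.get(data=newick, schema="newick",
                          rooting="default-rooted")
    return Phylogeny(tree=t)


BALANCED4 = "((a:1,b:1):2,(c:2,d:2):1);"


class TestNewickIo:
    def test_round_trip(self, tmp_path, yule44):
        p = tmp_path / "t.nwk"
        write_newick(yule44, str(p))
        back = read_newick(str(p))
        assert sorted(back.taxon_labels) == sorted(yule44.taxon_labels)
        la, Ca = bm_covariance(yule44)
        lb, Cb = bm_covariance(back)
        assert la == lb
        assert np.allclose(Ca, Cb, atol=1e-9)

    def test_malformed_newick_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((a:1,b:1)")
        with pytest.raises(Exception):
            read_newick(str(p))

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            _tree_from_string("((a,b),(c,d));")

    def test_duplicate_taxa_rejected(self):
        # dendropy already refuses duplicate tip labels at parse time
        with pytest.raises(Exception, match="[Mm]ultiple occurrences|[Dd]uplicate"):
            _tree_from_string("((a:1,a:1):1,b:2);")

    def test_name_normalization(self):
        assert normalize_name("Canis  lupus") == "canis_lupus"
        assert normalize_name("Canis_lupus") == "canis_lupus"


class TestBmCovariance:
    def test_balanced_four_taxon_tree(self):
        labels, C = bm_covariance(_tree_from_string(BALANCED4))
        i = {lab: k for k, lab in enumerate(labels)}
        assert C[i["a"], i["a"]] == pytest.approx(3.0)
        assert C[i["a"], i["b"]] == pytest.approx(2.0)
        assert C[i["c"], i["d"]] == pytest.approx(1.0)
        assert C[i["a"], i["c"]] == pytest.approx(0.0)
        assert np.allclose(C, C.T)

    def test_cherry(self):
        labels, C = bm_covariance(_tree_from_string("(a:1.5,b:1.5);"))
        assert np.allclose(C, 1.5 * np.eye(2))

    def test_yule_tree_psd_and_ultrametric_diagonal(self, yule44):
        _, C = bm_covariance(yule44)
        assert np.all(np.linalg.eigvalsh(C) > 0)
        assert np.ptp(np.diag(C)) < 1e-9 * C[0, 0]
        assert yule44.is_ultrametric()

    def test_matches_dendropy_phylogenetic_distances(self, yule44):
        """Oracle: C_ij = (depth_i + depth_j - patristic_ij) / 2."""
        labels, C = bm_covariance(yule44)
        pdm = yule44.tree.phylogenetic_distance_matrix()
        taxa = {normalize_name(t.label): t for t in yule44.tree.taxon_namespace}
        for i in range(0, 44, 7):
            for j in range(0, 44, 11):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                expected = (C[i, i] + C[j, j] - d) / 2
                assert C[i, j] == pytest.approx(expected, abs=1e-9)


class TestLambdaTransform:
    def test_lambda_one_is_identity(self, yule44):
        _, C = bm_covariance(yule44)
        assert np.array_equal(lambda_transform(C, 1.0), C)

    def test_lambda_zero_is_diagonal(self, yule44):
        _, C = bm_covariance(yule44)
        assert np.array_equal(lambda_transform(C, 0.0), np.diag(np.diag(C)))

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_out_of_range_rejected(self, yule44, lam):
        _, C = bm_covariance(yule44)
        with pytest.raises(ValueError):
            lambda_transform(C, lam)


def _bm_trait(C, lam, rng, mean=0.0, scale=1.0):
    V = lambda_transform(C, lam)
    return mean + scale * np.linalg.cholesky(V) @ rng.standard_normal(len(C))


class TestFitLambda:
    def test_likelihood_matches_dense_mvn_oracle(self, rng):
        """Profile log-likelihood equals scipy's MVN density at the same
        (mean, sigma^2) on a 6-taxon tree, across the lambda grid."""
        phy = _tree_from_string(
            "(((a:1,b:1):1,(c:1.5,d:1.5):0.5):1,(e:2,f:2):1);")
        labels, C = bm_covariance(phy)
        y = _bm_trait(C, 0.8, rng)
        X = np.ones((6, 1))
        for lam in [0.0, 0.3, 0.7, 1.0]:
            V = lambda_transform(C, lam)
            logl, beta, sigma2 = _gls_profile_loglik(y, X, V)
            oracle = stats.multivariate_normal.logpdf(
                y, mean=np.full(6, beta[0]), cov=sigma2 * V)
            assert logl == pytest.approx(oracle, abs=1e-9)

    def test_iid_trait_gives_lambda_near_zero(self, rng):
        tree = ls.simulate_tree(64, seed=5)
        labels, _ = bm_covariance(tree)
        trait = dict(zip(labels, rng.standard_normal(64)))
        est = fit_lambda_ml(trait, tree)
        assert est.lam < 0.25
        assert est.ci[1] < 1.0  # CI excludes strong signal

    def test_bm_trait_gives_lambda_near_one(self, yule44, rng):
        labels, C = bm_covariance(yule44)
        trait = dict(zip(labels, _bm_trait(C, 1.0, rng)))
        est = fit_lambda_ml(trait, yule44)
        assert est.lam > 0.8
        assert est.ci[0] > 0.3

    def test_ci_brackets_estimate(self, yule44, rng):
        labels, C = bm_covariance(yule44)
        for lam in [0.0, 0.9, 1.0]:
            trait = dict(zip(labels, _bm_trait(C, lam, rng)))
            est = fit_lambda_ml(trait, yule44)
            assert est.ci[0] <= est.lam <= est.ci[1]
            assert 0.0 <= est.ci[0] and est.ci[1] <= 1.0

    def test_constant_trait_rejected(self, yule44):
        labels, _ = bm_covariance(yule44)
        with pytest.raises(ValueError, match="constant"):
            fit_lambda_ml(dict.fromkeys(labels, 1.0), yule44)

    def test_too_few_tips_rejected(self):
        phy = _tree_from_string("((a:1,b:1):1,c:2);")
        with pytest.raises(ValueError, match="at least 4"):
            fit_lambda_ml({"a": 1.0, "b": 2.0, "c": 0.5}, phy)

    def test_taxa_mismatch_rejected(self, yule44):
        with pytest.raises(ValueError, match="missing"):
            fit_lambda_ml({"not_a_tip": 1.0}, yule44)


class TestResidualSignal:
    def test_structured_residuals_detected(self, yule44, rng):
        labels, C = bm_covariance(yule44)
        x = rng.standard_normal(44)
        resid = _bm_trait(C, 1.0, rng, scale=0.3)
        y = 0.4 * x + resid
        est = residual_signal_test(dict(zip(labels, y)),
                                   dict(zip(labels, x)), yule44)
        assert est.lam > 0.6

    def test_iid_residuals_not_detected(self, yule44, rng):
        labels, _ = bm_covariance(yule44)
        x = rng.standard_normal(44)
        y = 0.4 * x + 0.3 * rng.standard_normal(44)
        est = residual_signal_test(dict(zip(labels, y)),
                                   dict(zip(labels, x)), yule44)
        assert est.ci[0] < 0.4  # CI reaches down toward zero


class TestPgls:
    def _xy(self, C, lam, rng, slope=0.4, intercept=-0.1, scale=0.2):
        x = rng.uniform(2, 5.5, len(C))
        y = intercept + slope * x + _bm_trait(C, lam, rng, scale=scale)
        return x, y

    def test_lambda_zero_equals_ols_exactly(self, yule44, rng):
        labels, C = bm_covariance(yule44)
        x, y = self._xy(C, 0.9, rng)
        fit = pgls_lambda_regression(dict(zip(labels, y)),
                                     dict(zip(labels, x)), yule44, lam=0.0)
        b_ols, a_ols = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(b_ols, abs=1e-12)
        assert fit.intercept == pytest.approx(a_ols, abs=1e-12)

    def test_lambda_one_equals_independent_contrasts(self, rng):
        """Oracle: PGLS(lambda=1) slope equals the PIC regression-through-
        origin slope (Felsenstein equivalence), across 20 random trees."""
        for seed in range(20):
            tree = ls.simulate_tree(12, seed=100 + seed)
            labels, C = bm_covariance(tree)
            x = _bm_trait(C, 1.0, rng)
            y = 0.5 * x + _bm_trait(C, 1.0, rng, scale=0.4)
            fit = pgls_lambda_regression(dict(zip(labels, y)),
                                         dict(zip(labels, x)), tree, lam=1.0)

            taxa = tree.tree.taxon_namespace
            cm = dendropy.ContinuousCharacterMatrix.from_dict(
                {normalize_name(t.label): [
                    float(x[labels.index(normalize_name(t.label))]),
                    float(y[labels.index(normalize_name(t.label))]),
                ] for t in taxa}, taxon_namespace=taxa)
            picx = continuous.PhylogeneticIndependentContrasts(tree.tree, cm)
            cx = np.array([nd.pic_contrast_standardized
                           for nd in picx.contrasts_tree(0).preorder_internal_node_iter()])
            cy = np.array([nd.pic_contrast_standardized
                           for nd in picx.contrasts_tree(1).preorder_internal_node_iter()])
            b_pic = float(cx @ cy / (cx @ cx))
            assert fit.slope == pytest.approx(b_pic, abs=1e-8)

    def test_joint_lambda_recovers_generating_value(self, yule44, rng):
        labels, C = bm_covariance(yule44)
        x, y = self._xy(C, 0.9, rng, scale=0.15)
        fit = pgls_lambda_regression(dict(zip(labels, y)),
                                     dict(zip(labels, x)), yule44)
        assert fit.slope_ci[0] <= 0.4 <= fit.slope_ci[1]
        assert fit.lambda_estimate.lam > 0.3

    def test_affine_invariance_of_lambda(self, yule44, rng):
        labels, C = bm_covariance(yule44)
        x, y = self._xy(C, 0.9, rng)
        f1 = pgls_lambda_regression(dict(zip(labels, y)),
                                    dict(zip(labels, x)), yule44)
        f2 = pgls_lambda_regression(dict(zip(labels, 10 * y + 3)),
                                    dict(zip(labels, x)), yule44)
        assert f2.lambda_estimate.lam == pytest.approx(f1.lambda_estimate.lam,
                                                       abs=1e-5)
        assert f2.slope == pytest.approx(10 * f1.slope, rel=1e-9)

    def test_constant_x_rejected(self, yule44):
        labels, _ = bm_covariance(yule44)
        with pytest.raises(ValueError, match="singular"):
            pgls_lambda_regression(dict(zip(labels, np.arange(44.0))),
                                   dict.fromkeys(labels, 2.0), yule44)


class TestUnityBranches:
    def test_idempotent_and_preserves_taxa(self, yule44):
        u1 = set_branch_lengths_unity(yule44)
        u2 = set_branch_lengths_unity(u1)
        assert sorted(u1.taxon_labels) == sorted(yule44.taxon_labels)
        _, C1 = bm_covariance(u1)
        _, C2 = bm_covariance(u2)
        assert np.array_equal(C1, C2)
        assert u1.mode == "unity"

    def test_original_untouched(self, yule44):
        _, before = bm_covariance(yule44)
        set_branch_lengths_unity(yule44)
        _, after = bm_covariance(yule44)
        assert np.array_equal(before, after)

    def test_diagonal_counts_edges(self):
        phy = set_branch_lengths_unity(_tree_from_string(BALANCED4))
        labels, C = bm_covariance(phy)
        i = {lab: k for k, lab in enumerate(labels)}
        assert C[i["a"], i["a"]] == pytest.approx(2.0)  # two edges to root


class TestFixtureConsistency:
    def test_fixture_taxa_match_tree(self, fixture_data):
        table, tree = fixture_data
        assert sorted(table["species"]) == sorted(tree.taxon_labels)

    def test_fixture_trait_has_signal(self, fixture_data):
        table, tree = fixture_data
        trait = dict(zip(table["species"], np.log10(table["forelimb_length"])))
        est = fit_lambda_ml(trait, tree)
        assert est.lam > 0.5
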