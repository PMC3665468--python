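import numpy as np
import pytest

from prefrank.models import (DistanceBasedModel, LuceModel, PhiComponentModel,
                             RankOrderedLogit, WeightedDistanceModel,
                             goodness_of_fit, log_C, luce_prob, mallows_log_C,
                             phi_log_C, select_model)
from prefrank.rankcore import RankingTable, all_rankings, rank_agg
from prefrank.rankdist import DistanceSpec, distance_matrix, stage_counts
from prefrank.simulate import sample_dbm, sample_luce, sample_phicom, sample_wdbm


class TestLuceProb:
    def test_worked_example(self):
        assert luce_prob([2, 1, 1], ordering=[1, 2, 3]) == pytest.approx(0.25)

    def test_uniform_utilities(self):
        for perm in all_rankings(3):
            assert luce_prob([1, 1, 1], ranking=perm) == pytest.approx(1 / 6)

    def test_normalization_random_utilities(self, rng):
        v = rng.uniform(0.2, 5.0, 4)
        total = sum(luce_prob(v, ranking=p) for p in all_rankings(4))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_utilities_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            luce_prob([1.0, 0.0, 1.0], ordering=[1, 2, 3])


class TestNormalizingConstants:
    def test_mallows_worked_value(self):
        assert np.exp(mallows_log_C(3, np.log(2))) == pytest.approx(2.625, abs=1e-12)

    def test_limits(self):
        assert np.exp(mallows_log_C(4, 25.0)) == pytest.approx(1.0, abs=1e-6)
        assert np.exp(mallows_log_C(4, 0.0)) == pytest.approx(24.0)

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_closed_forms_match_enumeration(self, k, rng):
        identity = np.arange(1, k + 1).astype(float)
        perms = all_rankings(k).astype(float)
        V = np.stack([stage_counts(p, identity) for p in perms])
        for _ in range(10):
            lam = rng.uniform(0.01, 3.0)
            assert mallows_log_C(k, lam) == pytest.approx(
                log_C("tau", k, lam), abs=1e-10)
            lams = rng.uniform(0.01, 3.0, k - 1)
            enum = np.log(np.exp(-(V @ lams)).sum())
            assert phi_log_C(k, lams) == pytest.approx(enum, abs=1e-10)

    def test_enumeration_limit_error(self):
        with pytest.raises(ValueError, match="k <= 8"):
            log_C("tau", 9, 1.0)

    @pytest.mark.parametrize("family, kw", [
        ("dbm-tau", {}), ("dbm-rho", {}), ("dbm-rho2", {}), ("dbm-foot", {}),
    ])
    def test_model_normalization(self, family, kw, rng):
        # sum of P(pi) over S_k is 1 for random parameters
        k = 5
        dtype = family.split("-")[1]
        lam = rng.uniform(0.05, 2.0)
        d = distance_matrix(all_rankings(k), np.arange(1, k + 1), DistanceSpec(dtype))
        p = np.exp(-lam * d - log_C(dtype, k, lam))
        assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_weighted_model_normalization(self, rng):
        k = 5
        for dtype in ("tau", "foot", "rho2"):
            w = tuple(rng.uniform(0.0, 2.0, k))
            spec = DistanceSpec(dtype, weights=w)
            d = distance_matrix(all_rankings(k), np.arange(1, k + 1), spec)
            p = np.exp(-d - log_C(spec, k))
            assert p.sum() == pytest.approx(1.0, abs=1e-10)


class TestLuceFit:
    def test_parameter_recovery(self):
        X = sample_luce([4, 2, 1, 1], 2000, seed=11)
        m = LuceModel().fit(X)
        ratios = m.util_ / m.util_[-1]
        assert np.allclose(ratios, [4, 2, 1, 1], rtol=0.10)
        assert m.converged_

    def test_symmetric_table_gives_equal_utilities(self):
        m = LuceModel().fit(rank_agg(all_rankings(4)))
        assert np.allclose(m.util_, m.util_[0], atol=1e-5)

    def test_mle_beats_truth_on_loglik(self):
        X = sample_luce([3, 2, 1], 300, seed=4)
        m = LuceModel().fit(X)
        table = rank_agg(X)
        truth_ll = float(sum(
            f * np.log(luce_prob([3, 2, 1], ranking=r))
            for r, f in zip(table.rankings, table.freq)))
        assert m.loglik_ >= truth_ll - 1e-9

    def test_multistart_agrees(self):
        X = sample_luce([5, 3, 2, 1, 1], 400, seed=8)
        lls = [LuceModel(n_restarts=0, random_state=s).fit(X).loglik_ for s in range(3)]
        assert max(lls) - min(lls) < 1e-6

    def test_degenerate_data_flagged(self):
        # item 4 always ranked last: its utility runs to the boundary
        rows = np.array([[1, 2, 3, 4], [2, 1, 3, 4], [1, 3, 2, 4]] * 10)
        with pytest.warns(UserWarning, match="boundary"):
            m = LuceModel(ref_item=1).fit(rows)
        assert m.boundary_

    def test_tied_rankings_rejected(self):
        t = RankingTable(np.array([[1.0, 2.5, 2.5]]), np.array([5]), allow_ties=True)
        with pytest.raises(ValueError, match="strict"):
            LuceModel().fit(t)


class TestRolFit:
    def test_reduces_to_luce_without_covariates(self):
        X = sample_luce([3, 2, 1, 1], 400, seed=2)
        lu = LuceModel().fit(X)
        rol = RankOrderedLogit().fit(X, np.empty((400, 0)))
        p_l = lu.util_ / lu.util_.sum()
        p_r = np.exp(rol.beta_[:, 0]) / np.exp(rol.beta_[:, 0]).sum()
        assert np.allclose(p_l, p_r, atol=1e-6)
        assert rol.loglik_ == pytest.approx(lu.loglik_, abs=1e-6)

    def test_recovers_covariate_effect_within_3se(self, rng):
        k, N = 4, 3000
        beta = np.zeros((k, 2))
        beta[0, 1] = 1.0                      # covariate shifts item 1's log-utility
        x = rng.integers(0, 2, (N, 1)).astype(float)
        logu = np.hstack([np.ones((N, 1)), x]) @ beta.T
        R = np.vstack([sample_luce(np.exp(logu[i]), 1, rng)[0] for i in range(N)])
        m = RankOrderedLogit().fit(R, x)
        assert abs(m.beta_[0, 1] - 1.0) < 3 * m.se_[0, 1]
        assert m.p_values_[0, 1] < 0.01

    def test_judge_order_irrelevant(self, rng):
        R = sample_luce([2, 1, 1], 150, seed=5)
        x = rng.standard_normal((150, 1))
        m1 = RankOrderedLogit().fit(R, x)
        perm = rng.permutation(150)
        m2 = RankOrderedLogit().fit(R[perm], x[perm])
        assert np.allclose(m1.beta_, m2.beta_, atol=1e-5)

    def test_collinear_covariates_named(self, rng):
        R = sample_luce([1, 1, 1], 50, seed=6)
        x = rng.standard_normal((50, 1))
        X = np.hstack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear.*covariate"):
            RankOrderedLogit().fit(R, X)


class TestDistanceBasedFit:
    def test_mallows_recovery(self):
        X = sample_dbm([1, 2, 3, 4], 1.0, 1000, "tau", seed=3)
        m = DistanceBasedModel("tau").fit(X)
        assert m.pi0_.tolist() == [1, 2, 3, 4]
        assert m.lambda_ == pytest.approx(1.0, rel=0.15)

    def test_uniform_data_gives_small_lambda(self):
        m = DistanceBasedModel("tau").fit(rank_agg(np.repeat(all_rankings(4), 3, axis=0)))
        assert m.lambda_ < 1e-4

    def test_single_ranking_hits_bound(self):
        t = RankingTable(np.array([[1, 2, 3, 4]]), np.array([50]))
        with pytest.warns(UserWarning, match="bound"):
            m = DistanceBasedModel("tau").fit(t)
        assert m.boundary_

    def test_kendall_beats_wrong_distance_on_mallows_data(self, rng):
        wins = 0
        for i in range(30):
            X = sample_dbm([2, 1, 3, 4], 1.2, 300, "tau", rng)
            ll_tau = DistanceBasedModel("tau").fit(X).loglik_
            ll_rho2 = DistanceBasedModel("rho2").fit(X).loglik_
            wins += ll_tau > ll_rho2
        assert wins >= 27

    def test_label_equivariance(self, rng):
        X = sample_dbm([3, 1, 2, 4], 0.8, 400, "tau", seed=10)
        m1 = DistanceBasedModel("tau").fit(X)
        gamma_inv = rng.permutation(4)
        m2 = DistanceBasedModel("tau").fit(X[:, gamma_inv])
        assert m2.pi0_.tolist() == m1.pi0_[gamma_inv].tolist()
        assert m2.lambda_ == pytest.approx(m1.lambda_, abs=1e-6)


class TestPhiComponentFit:
    def test_stagewise_recovery(self):
        X = sample_phicom([1, 2, 3, 4], [2.0, 0.5, 0.5], 2000, seed=12)
        m = PhiComponentModel().fit(X)
        assert m.pi0_.tolist() == [1, 2, 3, 4]
        assert np.allclose(m.lambdas_, [2.0, 0.5, 0.5], rtol=0.20)
        assert m.lambdas_[0] > m.lambdas_[1]

    def test_equal_lambda_nests_mallows(self):
        # with all stage sums equal to Mallows' structure, constrained phicom
        # loglik at (lam,...,lam) equals the Mallows loglik at lam
        X = sample_dbm([1, 2, 3, 4], 0.9, 500, "tau", seed=13)
        dbm = DistanceBasedModel("tau").fit(X)
        table = rank_agg(X)
        V = np.stack([stage_counts(r, dbm.pi0_.astype(float)) for r in table.rankings])
        S = table.freq @ V
        lam = dbm.lambda_
        ll_constrained = -lam * S.sum() - table.n * phi_log_C(4, [lam] * 3)
        assert ll_constrained == pytest.approx(dbm.loglik_, abs=1e-6)


class TestWeightedFit:
    def test_rank1_agreement_detected(self):
        X = sample_wdbm([1, 2, 3, 4], [3, 0.2, 0.2, 0.2], 1000, "foot", seed=14)
        m = WeightedDistanceModel("foot").fit(X)
        assert m.pi0_.tolist() == [1, 2, 3, 4]
        assert np.argmax(m.weights_) == 0

    def test_constant_weights_nest_dbm(self):
        # wdbm at w = lam * 1 reproduces the footrule dbm loglik exactly
        X = sample_dbm([2, 1, 3, 4], 0.7, 500, "foot", seed=15)
        dbm = DistanceBasedModel("foot").fit(X)
        table = rank_agg(X)
        w = tuple([dbm.lambda_] * 4)
        spec = DistanceSpec("foot", weights=w)
        data = table.freq @ distance_matrix(table.rankings, dbm.pi0_, spec)
        ll = -data - table.n * log_C(spec, 4)
        assert ll == pytest.approx(dbm.loglik_, abs=1e-6)
        # and the free fit can only improve on the constrained one
        free = WeightedDistanceModel("foot").fit(table)
        assert free.loglik_ >= ll - 1e-6


class TestGoodnessOfFit:
    def test_hand_example_uniform(self):
        t = RankingTable(np.array([[1, 2, 3]]), np.array([2]))
        chi2, df = goodness_of_fit(t, "uniform")
        assert chi2 == pytest.approx(10.0)
        assert df == 5

    def test_balanced_table_uniform_fit_zero(self):
        t = rank_agg(np.repeat(all_rankings(3), 4, axis=0))
        chi2, _ = goodness_of_fit(t, "uniform")
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_df_subtracts_parameters(self):
        X = sample_dbm([1, 2, 3, 4], 1.0, 300, "tau", seed=16)
        m = DistanceBasedModel("tau").fit(X)
        assert m.gof_df_ == 24 - 1 - 1
        lu = LuceModel().fit(X)
        assert lu.gof_df_ == 24 - 1 - 3


class TestSelectModel:
    def test_single_and_nested(self):
        X = sample_dbm([1, 2, 3, 4], 1.0, 400, "tau", seed=17)
        dbm = DistanceBasedModel("tau").fit(X)
        phi = PhiComponentModel().fit(X)
        assert select_model([dbm.result()]).family == "dbm(tau)"
        # phicom nests Mallows: its loglik cannot be lower
        assert phi.loglik_ >= dbm.loglik_ - 1e-6
        best = select_model([dbm, phi])
        assert best.family == "phicom"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no fits"):
            select_model([])
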