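import numpy as np
import pytest
import scipy.stats as sps

from phyconiche.bisse import (
    BisseError,
    BisseParams,
    bisse_loglik,
    fit_ml,
    mcmc,
    summarize_rates,
)
from phyconiche.synthetic import simulate_bisse_tree
from phyconiche.trees import read_newick, tip_state_array, tree_to_arrays

from oracles import bd_mk2_loglik


@pytest.fixture(scope="module")
def medium_tree():
    p = BisseParams(1.0, 1.0, 0.2, 0.2, 0.15, 0.1)
    return simulate_bisse_tree(p, max_tips=60, seed=202)


class TestLoglik:
    def test_state_label_swap_symmetry(self, medium_tree):
        p = BisseParams(0.9, 0.5, 0.2, 0.1, 0.3, 0.15)
        swapped = BisseParams(0.5, 0.9, 0.1, 0.2, 0.15, 0.3)
        ll = bisse_loglik(medium_tree, p, root_mode="flat")
        flipped = read_newick(medium_tree.as_newick(),
                              {t: 1 - s for t, s in medium_tree.tip_states.items()})
        ll_swapped = bisse_loglik(flipped, swapped, root_mode="flat")
        assert ll == pytest.approx(ll_swapped, abs=1e-7)

    def test_impossible_history_is_minus_infinity(self):
        # no transitions possible, mixed tip states, root forced to state 0
        tree = read_newick("((A:1,B:1):1,C:2);", {"A": 0, "B": 1, "C": 0})
        p = BisseParams(1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
        assert bisse_loglik(tree, p, root_mode="fixed0") == -np.inf

    def test_factorization_oracle_single_tree(self, medium_tree):
        lam, mu, q01, q10 = 0.8, 0.3, 0.2, 0.1
        p = BisseParams(lam, lam, mu, mu, q01, q10)
        arr = tree_to_arrays(medium_tree)
        states = tip_state_array(medium_tree, arr)
        ll = bisse_loglik(medium_tree, p, root_mode="obs")
        oracle = bd_mk2_loglik(arr, states, lam, mu, q01, q10, root_mode="obs")
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_loglik_smooth_in_rates(self, medium_tree):
        base = np.array([0.8, 0.6, 0.2, 0.1, 0.15, 0.1])
        h = 1e-5
        for k in range(6):
            up, down = base.copy(), base.copy()
            up[k] += h
            down[k] -= h
            llu = bisse_loglik(medium_tree, BisseParams.from_array(up))
            lld = bisse_loglik(medium_tree, BisseParams.from_array(down))
            ll0 = bisse_loglik(medium_tree, BisseParams.from_array(base))
            # central value sits between the one-sided secants -> no jumps
            assert abs((llu - lld) / (2 * h)) < 1e5
            assert min(llu, lld) - 1.0 < ll0 < max(llu, lld) + 1.0

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            BisseParams(-0.1, 1, 0, 0, 0.1, 0.1)

    def test_nonbinary_tree_rejected(self):
        tree = read_newick("(A:1,B:1,C:1);", {"A": 0, "B": 0, "C": 1})
        with pytest.raises(Exception, match="bifurcating"):
            bisse_loglik(tree, BisseParams(1, 1, 0, 0, 0.1, 0.1))


class TestFitMl:
    def test_free_model_never_below_constrained(self):
        for seed in (5, 6):
            tree = simulate_bisse_tree(
                BisseParams(0.9, 0.4, 0.1, 0.1, 0.2, 0.2), max_tips=80, seed=seed
            )
            fit = fit_ml(tree)
            assert fit.loglik >= fit.constrained_loglik - 1e-6

    def test_likelihood_ratio_calibrated_under_constrained_truth(self):
        # data simulated under equal rates: 2Δloglik ~ chi² with 2 df
        crit = sps.chi2.ppf(0.95, df=2)
        rejections = 0
        n_rep = 25
        for seed in range(n_rep):
            tree = simulate_bisse_tree(
                BisseParams(0.8, 0.8, 0.1, 0.1, 0.2, 0.2), max_tips=70,
                seed=3000 + seed,
            )
            fit = fit_ml(tree)
            stat = 2 * (fit.loglik - fit.constrained_loglik)
            rejections += stat > crit
        # 5% nominal rate; allow generous binomial noise at 25 replicates
        assert rejections <= 5

    def test_small_tree_warns(self, caplog):
        tree = simulate_bisse_tree(
            BisseParams(1, 1, 0, 0, 0.2, 0.2), max_tips=10, seed=1
        )
        with caplog.at_level("WARNING"):
            fit_ml(tree)
        assert any("unstable" in r.message for r in caplog.records)


class TestMcmc:
    def test_trace_reproducible_under_fixed_seed(self, medium_tree):
        a = mcmc(medium_tree, n_iter=60, seed=4)
        b = mcmc(medium_tree, n_iter=60, seed=4)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_posterior_consistent_with_ml(self):
        tree = simulate_bisse_tree(
            BisseParams(0.9, 0.45, 0.1, 0.1, 0.2, 0.2), max_tips=150, seed=77
        )
        fit = fit_ml(tree)
        trace = mcmc(tree, n_iter=600, seed=8, start=fit.ml_params)
        burn = trace.iloc[300:].drop(columns="log_posterior")
        means = burn.mean().to_numpy()
        sds = burn.std().to_numpy()
        mlvec = fit.ml_params.as_array()
        assert (np.abs(means - mlvec) <= 2.5 * sds + 1e-6).all()

    def test_short_and_long_chains_agree_on_rate_ordering(self):
        tree = simulate_bisse_tree(
            BisseParams(0.9, 0.3, 0.05, 0.05, 0.15, 0.15), max_tips=120, seed=99
        )
        fit = fit_ml(tree)
        short = mcmc(tree, n_iter=1000, seed=21, start=fit.ml_params)
        long = mcmc(tree, n_iter=5000, seed=22, start=fit.ml_params)
        s = short.iloc[500:].mean()
        l = long.iloc[2500:].mean()
        assert (s["lambda0"] > s["lambda1"]) == (l["lambda0"] > l["lambda1"])


class TestSummarizeRates:
    def _fit(self, converged=True):
        from phyconiche.bisse import BisseFit

        return BisseFit(
            ml_params=BisseParams(2.0, 2.0, 0.5, 0.5, 0.1, 0.1),
            loglik=-10.0,
            converged=converged,
            constrained_start=BisseParams(1, 1, 0.5, 0.5, 0.1, 0.1),
            constrained_loglik=-12.0,
            n_tips=50,
            root_mode="obs",
        )

    def test_net_diversification_is_difference(self):
        rates = summarize_rates(self._fit())
        assert rates.loc["generalist", "net_diversification"] == pytest.approx(1.5)

    def test_symmetric_params_give_identical_rows(self):
        rates = summarize_rates(self._fit())
        assert (
            rates.loc["generalist"].to_numpy()
            == rates.loc["specialist"].to_numpy()
        ).all()

    def test_labels_follow_configured_mapping(self):
        rates = summarize_rates(self._fit(), {0: "broad", 1: "narrow"})
        assert list(rates.index) == ["broad", "narrow"]

    def test_unconverged_fit_refused(self):
        with pytest.raises(BisseError, match="unconverged"):
            summarize_rates(self._fit(converged=False))
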