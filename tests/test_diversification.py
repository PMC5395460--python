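"""Diversification likelihoods, model selection, and clade rate comparison."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from cycadrisk import (
    clade_rate_comparison,
    fit_all_models,
    fit_rate_constant,
    fit_rate_variable,
    parse_newick,
    piecewise_yule_loglik,
    select_model,
)
from cycadrisk.diversification import (
    DiversificationError,
    DiversificationFit,
    N_PARAMS,
    _BTStats,
    _bd_loglik,
    _pure_birth_loglik,
)
from cycadrisk.simulate import SimConfig, simulate_tree
from cycadrisk.tree import branching_times


@pytest.fixture(scope="module")
def yule_bt():
    tree = simulate_tree(SimConfig(seed=21, n_species=120, birth=0.1))
    return branching_times(tree)


class TestPiecewiseYule:
    def test_equal_rates_collapse_to_pure_birth(self, yule_bt):
        r = 0.13
        base = piecewise_yule_loglik(yule_bt, [r], [])
        one_shift = piecewise_yule_loglik(yule_bt, [r, r], [yule_bt[0] / 2])
        two_shifts = piecewise_yule_loglik(
            yule_bt, [r, r, r], [yule_bt[0] * 0.6, yule_bt[0] * 0.3]
        )
        assert one_shift == pytest.approx(base, abs=1e-9)
        assert two_shifts == pytest.approx(base, abs=1e-9)

    def test_tiny_worked_tree(self):
        base = piecewise_yule_loglik([2.0, 1.0], [0.5], [])
        assert piecewise_yule_loglik([2.0, 1.0], [0.5, 0.5], [1.5]) == pytest.approx(base)

    def test_shift_outside_root_age_rejected(self, yule_bt):
        with pytest.raises(DiversificationError, match="inside"):
            piecewise_yule_loglik(yule_bt, [0.1, 0.2], [yule_bt[0] * 2])

    def test_truth_beats_swapped_rates_on_two_era_trees(self):
        # the shift at t=12 (~22 expected lineages) always happens before the
        # 300-tip stop, so both eras hold many events in every replicate
        wins, n = 0, 60
        for rep in range(n):
            cfg = SimConfig(seed=4000 + rep, n_species=300, birth=0.2,
                            shift_times=(12.0,), shift_rates=(0.02,))
            bt = branching_times(simulate_tree(cfg))
            shift_age = bt[0] - 12.0
            assert 0 < shift_age < bt[0]
            at_truth = piecewise_yule_loglik(bt, [0.2, 0.02], [shift_age])
            swapped = piecewise_yule_loglik(bt, [0.02, 0.2], [shift_age])
            wins += at_truth > swapped
        assert wins >= 0.95 * n


class TestRateConstant:
    def test_pure_birth_closed_form_matches_numeric_optimum(self):
        bt = [2.0, 1.0]
        st = _BTStats(bt)
        fit = fit_rate_constant(bt)["pureBirth"]
        res = optimize.minimize_scalar(
            lambda r: -_pure_birth_loglik(st, r), bounds=(1e-6, 10), method="bounded"
        )
        assert fit.params["r"] == pytest.approx(res.x, abs=1e-6)
        assert fit.lnl == pytest.approx(-res.fun, abs=1e-9)

    def test_bd_collapses_to_pure_birth_at_zero_extinction(self, yule_bt):
        st = _BTStats(yule_bt)
        for r in (0.05, 0.1, 0.3):
            assert _bd_loglik(st, r, 0.0) == pytest.approx(
                _pure_birth_loglik(st, r), abs=1e-6
            )

    def test_bd_fit_never_below_pure_birth(self, yule_bt):
        fits = fit_rate_constant(yule_bt, seed=0)
        assert fits["bd"].lnl >= fits["pureBirth"].lnl - 1e-6

    def test_rate_recovery_median(self):
        # median pure-birth estimate within [0.08, 0.12] at r=0.1, n=200
        r_hats = []
        for rep in range(100):
            tree = simulate_tree(SimConfig(seed=6000 + rep, n_species=200, birth=0.1))
            bt = branching_times(tree)
            r_hats.append(fit_rate_constant(bt)["pureBirth"].params["r"])
        assert 0.08 <= float(np.median(r_hats)) <= 0.12


class TestRateVariable:
    def test_ddx_at_x_zero_equals_pure_birth(self, yule_bt):
        st = _BTStats(yule_bt)
        from cycadrisk.diversification import _rate_by_k_profile

        r0, lnl = _rate_by_k_profile(st, lambda k: np.asarray(k) ** 0.0)
        pb = fit_rate_constant(yule_bt)["pureBirth"]
        assert lnl == pytest.approx(pb.lnl, abs=1e-9)
        assert r0 == pytest.approx(pb.params["r"], abs=1e-9)

    def test_ddl_with_huge_k_approaches_pure_birth(self, yule_bt):
        st = _BTStats(yule_bt)
        from cycadrisk.diversification import _rate_by_k_profile

        K = 1e9
        r0, lnl = _rate_by_k_profile(st, lambda k: 1.0 - np.asarray(k) / K)
        pb = fit_rate_constant(yule_bt)["pureBirth"]
        assert lnl == pytest.approx(pb.lnl, abs=1e-3)

    def test_fitted_rv_models_at_least_as_good_as_pure_birth(self, yule_bt):
        fits = fit_rate_variable(yule_bt)
        pb = fit_rate_constant(yule_bt)["pureBirth"]
        for name in ("DDL", "DDX"):
            assert fits[name].lnl >= pb.lnl - 1e-6
        assert fits["DDL"].params["K"] > len(yule_bt) + 1

    def test_yule2_shift_strictly_inside(self, yule_bt):
        fit = fit_rate_variable(yule_bt)["yule2rate"]
        assert 0 < fit.params["st"] < yule_bt[0]
        assert fit.params["r1"] > 0 and fit.params["r2"] > 0


class TestSelection:
    def test_aic_bookkeeping(self, yule_bt):
        fits = fit_all_models(yule_bt, seed=0)
        for name, fit in fits.items():
            assert fit.aic == pytest.approx(2 * N_PARAMS[name] - 2 * fit.lnl)

    def test_tie_goes_to_rate_constant(self):
        a = DiversificationFit("pureBirth", {"r": 0.1}, -10.0, 22.0)
        b = DiversificationFit("yule2rate", {}, -8.0, 22.0)
        sel = select_model([a, b])
        assert sel.delta_aic_rc == 0.0
        assert sel.verdict == "rate_constant"

    def test_strong_two_era_trees_detected(self):
        hits, n = 0, 40
        for rep in range(n):
            cfg = SimConfig(seed=3000 + rep, n_species=300, birth=0.2,
                            shift_times=(20.0,), shift_rates=(0.02,))
            bt = branching_times(simulate_tree(cfg))
            hits += select_model(fit_all_models(bt, seed=0)).verdict == "rate_variable"
        assert hits >= 0.9 * n

    def test_missing_family_rejected(self, yule_bt):
        with pytest.raises(DiversificationError, match="family"):
            select_model([fit_rate_constant(yule_bt)["pureBirth"]])


class TestCladeRateComparison:
    @staticmethod
    def _two_clade_tree(rng, n_each=30, scale_left=1.0):
        left = ",".join(
            f"L{i}:{scale_left * rng.exponential(1.0):.6f}" for i in range(n_each)
        )
        right = ",".join(f"R{i}:{rng.exponential(1.0):.6f}" for i in range(n_each))
        return parse_newick(f"(({left}):1,({right}):1);")

    def test_equal_means_give_zero_lrt(self):
        t = parse_newick("((A:1,B:1,C:1):1,(D:1,E:1,F:1):1);")
        node = [i for i in range(t.n_nodes) if len(t.children(i)) == 3][0]
        res = clade_rate_comparison(t, node)
        assert res.lrt == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_null_p_uniform_when_distributions_match(self):
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            t = self._two_clade_tree(rng)
            node = t.children(t.root)[0]
            ps.append(clade_rate_comparison(t, node).p_value)
        assert abs(np.mean(ps) - 0.5) < 0.1
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_fast_clade_flagged_hot(self):
        hot = 0
        for rep in range(40):
            rng = np.random.default_rng(10_000 + rep)
            t = self._two_clade_tree(rng, scale_left=0.1)
            node = t.children(t.root)[0]
            res = clade_rate_comparison(t, node, alpha=0.01)
            hot += res.hot and res.p_value < 0.01
        assert hot >= 0.95 * 40

    def test_degenerate_branch_sets_rejected(self):
        t = parse_newick("((A:0,B:0,C:0):0,(D:1,E:1,F:1):1);")
        node = [
            i for i in range(t.n_nodes)
            if len(t.children(i)) == 3 and t.labels[t.children(i)[0]] == "A"
        ][0]
        with pytest.raises(DiversificationError, match="zero total length"):
            clade_rate_comparison(t, node)
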