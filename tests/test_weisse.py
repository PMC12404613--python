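"""Mechanistic ODE growth model: kinetics, steady states, mutational
scans, and the transcription-nonlinearity (gamma) sweep."""

import numpy as np
import pytest

from neutrality import weisse as W


class TestDerivatives:
    def test_no_translating_ribosomes_means_no_growth(self, weisse_wt):
        params, _ = weisse_wt
        state = W.default_initial_state(params)
        state[3:11] = 0.0  # no mRNA, no complexes
        assert W.growth_rate_of_state(state, params) == 0.0
        d = W.derivatives(state, params)
        # no translation flux: proteins only dilute (lambda = 0 here)
        assert d[11] == d[12] == d[13] == 0.0

    def test_growth_rate_inversely_proportional_to_mass(self, weisse_wt):
        params, ss = weisse_wt
        from dataclasses import replace

        doubled = replace(params, M=2 * params.M)
        assert W.growth_rate_of_state(ss.state, doubled) == pytest.approx(
            0.5 * ss.rate, rel=1e-12
        )

    def test_negative_state_rejected(self, weisse_wt):
        params, _ = weisse_wt
        state = W.default_initial_state(params)
        state[0] = -1.0
        with pytest.raises(ValueError):
            W.derivatives(state, params)

    def test_steady_state_flux_balances(self, weisse_wt):
        """At the converged state: energy production equals translation
        consumption plus dilution, and total protein mass equals M."""
        params, ss = weisse_wt
        s_i, a = ss.state[0], ss.state[1]
        p_m = ss.state[12]
        v_cat = p_m * params.v_m * s_i / (params.K_m + s_i)
        g_a = params.g_max * a / (params.K_p + a)
        c_tot = ss.state[7:11].sum()
        assert params.n_s * v_cat == pytest.approx(
            g_a * c_tot + ss.rate * a, rel=1e-6
        )
        mass = params.n_x * ss.state[11:].sum() + params.n_r * (
            ss.state[2] + c_tot
        )
        assert mass == pytest.approx(params.M, rel=1e-6)


class TestSteadyState:
    def test_wild_type_growth_rate_is_physiological(self, weisse_wt):
        # doubling time of tens of minutes on rich medium
        _, ss = weisse_wt
        assert 0.005 < ss.rate < 0.1

    def test_integration_and_root_agree(self, weisse_wt):
        """Dual-solver oracle: stiff integration and the reduced algebraic
        system agree to < 1e-6 relative on the wild type and on random
        deleterious mutants."""
        params, wt = weisse_wt
        lam_int = W.steady_state_growth(params, solver="integrate").rate
        assert abs(lam_int - wt.rate) / wt.rate < 1e-6
        rng = np.random.default_rng(21)
        targets = sorted(W.MUTABLE_PARAMS)
        for _ in range(6):
            target = targets[rng.integers(len(targets))]
            theta = 1.0 - 0.9 * rng.random()
            mp = W.mutate(params, target, theta)
            lam_root = W.steady_state_growth(mp, guess=wt, ref_params=params).rate
            lam_int = W.steady_state_growth(mp, solver="integrate").rate
            assert abs(lam_int - lam_root) / lam_root < 1e-6

    def test_invalid_solver_rejected(self, weisse_wt):
        with pytest.raises(ValueError):
            W.steady_state_growth(weisse_wt[0], solver="magic")


class TestMutate:
    def test_theta_one_is_identity(self, weisse_wt):
        params, _ = weisse_wt
        assert W.mutate(params, "v_t", 1.0) == params

    def test_shrink_and_grow_directions(self, weisse_wt):
        params, _ = weisse_wt
        assert W.mutate(params, "v_t", 0.5).v_t == pytest.approx(params.v_t / 2)
        assert W.mutate(params, "K_p", 0.5).K_p == pytest.approx(2 * params.K_p)

    def test_unknown_target_lists_mutable_set(self, weisse_wt):
        with pytest.raises(ValueError, match="g_max"):
            W.mutate(weisse_wt[0], "n_r", 0.5)

    def test_every_mutable_direction_is_deleterious(self, weisse_wt):
        """Halving (or doubling, for grow-direction parameters) any of the
        9 mutable parameters does not increase growth; v_t strictly
        decreases it."""
        params, wt = weisse_wt
        for target in W.MUTABLE_PARAMS:
            ss = W.steady_state_growth(
                W.mutate(params, target, 0.5), guess=wt, ref_params=params
            )
            assert ss.rate <= wt.rate * (1 + 1e-6), target
        halved = W.steady_state_growth(
            W.mutate(params, "v_t", 0.5), guess=wt, ref_params=params
        )
        assert halved.rate < wt.rate


class TestPairScan:
    def test_same_process_pair_rejected(self):
        with pytest.raises(ValueError, match="same process"):
            W.pair_scan(("g_max", "K_p"), n=1)
        with pytest.raises(ValueError, match="same process"):
            W.pair_scan(("v_t", "v_m"), n=1)

    def test_cross_process_pairs_number_twenty_eight(self):
        pairs = W.cross_process_pairs()
        assert len(pairs) == 28
        procs = {W.MUTABLE_PARAMS[a][0] for a, _ in pairs}
        assert len({p for p, _ in W.MUTABLE_PARAMS.values()}) == 4

    def test_scan_deterministic_and_bounded(self, weisse_wt):
        params, wt = weisse_wt
        a = W.pair_scan(("v_t", "n_s"), n=20, seed=8, params=params, wt=wt)
        b = W.pair_scan(("v_t", "n_s"), n=20, seed=8, params=params, wt=wt)
        assert a.table.equals(b.table)
        for col in ("w_x", "w_y", "w_xy"):
            assert (a.table[col] > 0).all()
            assert (a.table[col] <= 1 + 1e-6).all()

    def test_metabolic_pair_follows_product_translation_pair_follows_closed_form(
        self, weisse_wt
    ):
        params, wt = weisse_wt
        metab = W.pair_scan(("v_t", "n_s"), n=80, seed=13, params=params, wt=wt)
        assert metab.mean_abs_dev["product"] < metab.mean_abs_dev["scott_hwa"]
        trans = W.pair_scan(("v_t", "g_max"), n=80, seed=13, params=params, wt=wt)
        assert trans.mean_abs_dev["scott_hwa"] < trans.mean_abs_dev["product"]


class TestGammaSweep:
    def test_single_gamma_single_row(self, weisse_wt):
        params, _ = weisse_wt
        tab = W.gamma_sweep([0.05], n=5, seed=2, params=params)
        assert len(tab) == 1
        assert tab["theta_x"].iloc[0] == pytest.approx(20.0)

    def test_product_fit_improves_as_gamma_decreases(self, weisse_wt):
        """Below the crossover where theta_x exceeds the steady-state
        energy scale, shrinking gamma makes transcription linear in energy
        and the Product law a better and better approximation."""
        params, _ = weisse_wt
        tab = W.gamma_sweep([0.1, 0.03, 0.01, 0.003], n=60, seed=17, params=params)
        med = tab["median_abs_product_residual"].to_numpy()
        assert (np.diff(med) < 0).all()

    def test_gamma_must_be_positive(self, weisse_wt):
        with pytest.raises(ValueError):
            W.gamma_sweep([0.1, -1.0], n=1, params=weisse_wt[0])


def test_params_asset_and_validation():
    p = W.WeisseParams.default()
    assert p.gamma == pytest.approx(1.0 / p.theta_x)
    assert p.with_gamma(0.5).theta_x == pytest.approx(2.0)
    with pytest.raises(ValueError):
        W.WeisseParams.default(v_t=-1.0)
    with pytest.raises(ValueError):
        p.with_gamma(0.0)
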