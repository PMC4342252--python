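"""Unit and property tests for the Hill terms and the delayed-system integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floranet import (
    REFERENCE_X0,
    SPECIES,
    InputProfiles,
    ParameterSet,
    evaluate_rhs,
    hill_activation,
    hill_repression,
    make_mutant,
    simulate,
    simulate_mutant,
)
from floranet.model import IDX


class TestHillTerms:
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_half_maximum(self, n):
        assert hill_activation(50.0, 50.0, n) == pytest.approx(0.5)

    def test_zero_and_saturation(self):
        assert hill_activation(0.0, 10.0, 3) == 0.0
        assert hill_activation(2 * 7.0, 7.0, 3) == pytest.approx(8.0 / 9.0)

    def test_repression_values(self):
        assert hill_repression(0.0, 10.0) == 1.0
        assert hill_repression(10.0, 10.0) == pytest.approx(0.5)
        assert hill_repression(30.0, 10.0) == pytest.approx(0.25)

    def test_degenerate_half_max_rejected(self):
        with pytest.raises(ValueError):
            hill_activation(1.0, 0.0)
        with pytest.raises(ValueError):
            hill_repression(1.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        x=st.floats(0, 1e6),
        k=st.floats(1e-3, 1e4),
        n=st.integers(1, 5),
    )
    def test_activation_bounded_and_monotone(self, x, k, n):
        v = hill_activation(x, k, n)
        assert 0.0 <= v <= 1.0  # mathematically < 1, but saturates in float
        assert hill_activation(x * 1.5 + 1.0, k, n) >= v

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(0, 1e6), k=st.floats(1e-3, 1e4))
    def test_repression_bounded_and_antitone(self, x, k):
        v = hill_repression(x, k)
        assert 0.0 < v <= 1.0
        assert hill_repression(x * 1.5 + 1.0, k) <= v


def decay_only_params(d=(0.3, 0.4, 0.45, 0.42, 0.5, 0.35)):
    return ParameterSet(beta=np.zeros(12), K=np.full(16, 50.0), d=list(d), delta=0.0, n=3)


class TestEvaluateRhs:
    def test_pure_decay(self, ref_params):
        p = decay_only_params()
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        inputs = InputProfiles.constant(flc=0.0, svp=0.0)
        deriv = evaluate_rhs(1.0, x, p, inputs)
        assert np.allclose(deriv, -p.d * x)

    def test_open_gates_give_full_ft_production(self, ref_params):
        inputs = InputProfiles.constant(flc=0.0, svp=0.0)
        x = np.zeros(6)
        deriv = evaluate_rhs(0.0, x, ref_params, inputs)
        assert deriv[IDX["FT"]] == pytest.approx(ref_params.beta[0])

    def test_agl24_at_half_max(self, ref_params):
        inputs = InputProfiles.constant(flc=0.0, svp=0.0)
        x = np.zeros(6)
        x[IDX["SOC1"]] = ref_params.K[2]  # K3 of the AGL24 equation
        deriv = evaluate_rhs(0.0, x, ref_params, inputs)
        assert deriv[IDX["AGL24"]] == pytest.approx(ref_params.beta[1] / 2)

    def test_clamped_species_have_zero_derivative(self, ref_params):
        inputs = InputProfiles.constant(flc=10.0, svp=10.0)
        x = np.full(6, 30.0)
        deriv = evaluate_rhs(0.0, x, ref_params, inputs, clamped={"SOC1": 30.0})
        assert deriv[IDX["SOC1"]] == 0.0


class TestSimulate:
    def test_decay_matches_closed_form(self):
        p = decay_only_params()
        inputs = InputProfiles.constant()
        x0 = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        traj = simulate(p, inputs, x0, rtol=1e-10, atol=1e-13)
        expected = x0[None, :] * np.exp(-p.d[None, :] * traj.days[:, None])
        assert np.allclose(traj.values, expected, rtol=1e-6, atol=1e-9)

    def test_zero_delay_matches_undelayed_ode(self, ref_params, inputs):
        """delta = 0 must reduce to the plain ODE with current-time FT."""
        from scipy.integrate import solve_ivp

        p0 = ref_params.replace(delta=0.0)
        traj = simulate(p0, inputs, REFERENCE_X0, rtol=1e-10, atol=1e-12)

        def rhs(t, x):
            return evaluate_rhs(t, np.maximum(x, 0), p0, inputs, ft_delayed=max(x[0], 0))

        x0 = np.array([REFERENCE_X0[g] for g in SPECIES])
        ref = solve_ivp(rhs, (0, 20), x0, method="LSODA", t_eval=traj.days,
                        rtol=1e-10, atol=1e-12)
        scale = np.maximum(np.abs(ref.y.T), 1.0)
        assert np.max(np.abs(traj.values - ref.y.T) / scale) < 1e-8

    def test_ft_steady_state_constant_inputs(self, ref_params):
        svp, flc = 80.0, 40.0
        inputs = InputProfiles.constant(flc=flc, svp=svp, span=(0, 200))
        traj = simulate(ref_params, inputs, REFERENCE_X0, horizon=(0, 200))
        b, K, d = ref_params.beta, ref_params.K, ref_params.d
        expected = b[0] * (K[0] / (K[0] + svp)) * (K[1] / (K[1] + flc)) / d[0]
        assert traj.column("FT")[-1] == pytest.approx(expected, rel=1e-4)

    def test_non_negative_and_bounded(self, ref_params, inputs, wt_traj):
        assert np.all(wt_traj.values >= 0)
        b, d = ref_params.beta, ref_params.d
        # per-equation production ceilings (sum of beta terms)
        caps = {
            "FT": b[0] / d[0],
            "AGL24": b[1] / d[1],
            "SOC1": (b[2] + b[3] + b[4]) / d[2],
            "LFY": (b[5] + b[6] + b[7]) / d[3],
            "AP1": (b[8] + b[9] + b[10]) / d[4],
            "FD": b[11] / d[5],
        }
        for gene, cap in caps.items():
            start = REFERENCE_X0[gene]
            assert wt_traj.column(gene).max() <= max(cap, start) * (1 + 1e-9)

    def test_grid_includes_requested_days(self, ref_params, inputs):
        days = np.array([0.0, 3.3, 12.6, 19.9])
        traj = simulate(ref_params, inputs, REFERENCE_X0, extra_days=days)
        assert np.all(np.isin(days, traj.days))

    def test_grid_refinement_converged(self, ref_params, inputs):
        coarse = simulate(ref_params, inputs, REFERENCE_X0, grid_step=0.1)
        fine = simulate(ref_params, inputs, REFERENCE_X0, grid_step=0.05)
        shared = np.intersect1d(coarse.days, fine.days)
        for g in SPECIES:
            a = np.interp(shared, coarse.days, coarse.column(g))
            b = np.interp(shared, fine.days, fine.column(g))
            assert np.max(np.abs(a - b)) < 1e-3 * max(1.0, b.max())

    def test_monotone_beta_response(self, ref_params, inputs, wt_traj):
        """Raising one activation strength cannot lower its target's integral."""
        for b_idx, gene in [(1, "AGL24"), (6, "LFY"), (8, "AP1"), (11, "FD")]:
            beta = ref_params.beta.copy()
            beta[b_idx] *= 1.5
            up = simulate(ref_params.replace(beta=beta.tolist()), inputs, REFERENCE_X0)
            base = np.trapezoid(wt_traj.column(gene), wt_traj.days)
            boosted = np.trapezoid(up.column(gene), up.days)
            assert boosted >= base * (1 - 1e-9)

    def test_delay_exceeding_horizon_rejected(self, ref_params, inputs):
        with pytest.raises(ValueError, match="delay"):
            simulate(ref_params.replace(delta=30.0), inputs, REFERENCE_X0)

    def test_negative_initial_state_rejected(self, ref_params, inputs):
        x0 = dict(REFERENCE_X0, FT=-1.0)
        with pytest.raises(ValueError):
            simulate(ref_params, inputs, x0)


class TestDimerVariant:
    def test_knockout_symmetry_under_dimer_only(self, ref_params, inputs):
        soc1 = simulate_mutant(ref_params, inputs, make_mutant("SOC1", "knockout"),
                               REFERENCE_X0, variant="dimer_only")
        agl24 = simulate_mutant(ref_params, inputs, make_mutant("AGL24", "knockout"),
                                REFERENCE_X0, variant="dimer_only")
        assert np.max(np.abs(soc1.column("LFY") - agl24.column("LFY"))) < 1e-3

    def test_knockouts_differ_under_independent(self, ref_params, inputs):
        soc1 = simulate_mutant(ref_params, inputs, make_mutant("SOC1", "knockout"),
                               REFERENCE_X0, variant="independent")
        agl24 = simulate_mutant(ref_params, inputs, make_mutant("AGL24", "knockout"),
                                REFERENCE_X0, variant="independent")
        assert np.max(np.abs(soc1.column("LFY") - agl24.column("LFY"))) > 1.0


class TestParameterSet:
    def test_free_parameter_count(self, ref_params):
        assert ref_params.n_free == 35

    def test_json_round_trip(self, tmp_path, ref_params):
        path = tmp_path / "params.json"
        ref_params.to_json(path)
        back = ParameterSet.from_json(path)
        assert np.allclose(back.beta, ref_params.beta)
        assert np.allclose(back.K, ref_params.K)
        assert np.allclose(back.d, ref_params.d)
        assert back.delta == ref_params.delta and back.n == ref_params.n

    @pytest.mark.parametrize(
        "bad",
        [
            dict(beta=np.zeros(11)),
            dict(K=np.zeros(15)),
            dict(d=np.zeros(5)),
            dict(delta=-1.0),
            dict(n=0),
        ],
    )
    def test_invariants_enforced(self, bad):
        payload = dict(beta=np.zeros(12), K=np.ones(16), d=np.ones(6), delta=1.0, n=3)
        payload.update(bad)
        with pytest.raises(ValueError):
            ParameterSet(**payload)
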