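"""Tests for mutant construction, clamped simulation, expression changes and
the permutation-based correlation test."""

import numpy as np
import pytest
from scipy import stats

from floranet import (
    REFERENCE_X0,
    SPECIES,
    beta_sensitivity_sweep,
    correlation_with_permutation_null,
    expression_change,
    make_mutant,
    predict_flowering,
    simulate_mutant,
)
from floranet.flowering import NO_FLOWERING


class TestMakeMutant:
    def test_knockout_clamp_is_zero(self):
        m = make_mutant("FT", "knockout")
        assert m.clamps == {"FT": 0.0}

    def test_overexpression_is_five_times_ceiling(self):
        m = make_mutant("SOC1", "overexpression")
        assert m.clamps == {"SOC1": 2500.0}

    def test_knockdown_fraction_of_first_point(self):
        m = make_mutant("SOC1", "knockdown", wt_first_point=80.0, fraction=0.1)
        assert m.clamps["SOC1"] == pytest.approx(8.0)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_bad_knockdown_fraction(self, fraction):
        with pytest.raises(ValueError):
            make_mutant("SOC1", "knockdown", wt_first_point=80.0, fraction=fraction)

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            make_mutant("XYZ", "knockout")

    def test_merge_builds_double_mutant(self):
        double = make_mutant("SOC1", "knockout").merge(make_mutant("AGL24", "knockout"))
        assert set(double.clamps) == {"SOC1", "AGL24"}

    def test_merge_rejects_conflicting_clamps(self):
        with pytest.raises(ValueError):
            make_mutant("SOC1", "knockout").merge(make_mutant("SOC1", "overexpression"))


class TestSimulateMutant:
    def test_clamped_species_constant_to_machine_precision(self, ref_params, inputs):
        m = make_mutant("SOC1", "overexpression")
        traj = simulate_mutant(ref_params, inputs, m, REFERENCE_X0)
        assert np.all(traj.column("SOC1") == 2500.0)

    def test_ft_knockout_clamps_delayed_occurrences(self, ref_params, inputs, wt_traj):
        """A null FT allele removes the FT.FD activation of SOC1 and AP1 as
        well as the leaf transcript."""
        m = make_mutant("FT", "knockout")
        traj = simulate_mutant(ref_params, inputs, m, REFERENCE_X0)
        assert np.all(traj.column("FT") == 0.0)
        # SOC1 loses its FT(t - delta).FD production term relative to wild type
        assert np.trapezoid(traj.column("SOC1"), traj.days) < np.trapezoid(
            wt_traj.column("SOC1"), wt_traj.days
        )

    def test_input_gene_mutant_rewrites_profiles(self, ref_params, inputs, wt_traj):
        """FLC overexpression represses FT: the mutant rewrites both tissue
        profiles rather than clamping a model state."""
        m = make_mutant("FLC", "overexpression")
        traj = simulate_mutant(ref_params, inputs, m, REFERENCE_X0)
        assert traj.column("FT")[-1] < 0.1 * wt_traj.column("FT")[-1]

    def test_double_knockout_leaves_only_ap1_feedback_on_lfy(self, ref_params, inputs):
        double = make_mutant("SOC1", "knockout").merge(make_mutant("AGL24", "knockout"))
        beta = ref_params.beta.copy()
        beta[7] = 0.0  # also silence the AP1 -> LFY feedback
        no_feedback = ref_params.replace(beta=beta.tolist())
        traj = simulate_mutant(no_feedback, inputs, double, REFERENCE_X0)
        # with all three LFY activators gone, LFY decays from its start value
        expected = REFERENCE_X0["LFY"] * np.exp(-ref_params.d[3] * traj.days)
        assert np.allclose(traj.column("LFY"), expected, rtol=1e-4, atol=1e-6)

    def test_soc1_hits_lfy_harder_than_agl24(self, ref_params, inputs, wt_traj):
        """SOC1 is the stronger LFY activator in the reference network."""
        soc1 = simulate_mutant(ref_params, inputs, make_mutant("SOC1", "knockout"), REFERENCE_X0)
        agl24 = simulate_mutant(ref_params, inputs, make_mutant("AGL24", "knockout"), REFERENCE_X0)
        drop_soc1 = expression_change(wt_traj, soc1, "LFY").relative_change
        drop_agl24 = expression_change(wt_traj, agl24, "LFY").relative_change
        assert drop_soc1 < drop_agl24 < 0

    def test_double_knockout_exceeds_single(self, ref_params, inputs, wt_traj):
        soc1 = simulate_mutant(ref_params, inputs, make_mutant("SOC1", "knockout"), REFERENCE_X0)
        double = simulate_mutant(
            ref_params, inputs,
            make_mutant("SOC1", "knockout").merge(make_mutant("AGL24", "knockout")),
            REFERENCE_X0,
        )
        assert (
            expression_change(wt_traj, double, "LFY").abs_relative_change
            >= expression_change(wt_traj, soc1, "LFY").abs_relative_change - 1e-12
        )

    def test_activator_knockout_never_raises_direct_target(self, ref_params, inputs, wt_traj):
        for gene, target in [("SOC1", "AGL24"), ("AGL24", "LFY"), ("FD", "AP1")]:
            mut = simulate_mutant(ref_params, inputs, make_mutant(gene, "knockout"), REFERENCE_X0)
            change = expression_change(wt_traj, mut, target)
            assert change.relative_change <= 1e-9


class TestExpressionChange:
    def test_identical_trajectories_give_zero(self, wt_traj):
        ch = expression_change(wt_traj, wt_traj, "LFY")
        assert ch.relative_change == 0.0

    def test_doubling_gives_plus_one(self, wt_traj):
        from floranet import Trajectory

        doubled = Trajectory(days=wt_traj.days, values=2 * wt_traj.values)
        ch = expression_change(wt_traj, doubled, "AP1")
        assert ch.relative_change == pytest.approx(1.0)
        assert ch.abs_relative_change == pytest.approx(1.0)

    def test_zero_wildtype_integral_rejected(self, wt_traj):
        from floranet import Trajectory

        zero = Trajectory(days=wt_traj.days, values=np.zeros_like(wt_traj.values))
        with pytest.raises(ValueError, match="zero"):
            expression_change(zero, wt_traj, "LFY")


class TestPermutationCorrelation:
    def test_identical_vectors_give_r_one(self):
        x = np.arange(10.0)
        r, p = correlation_with_permutation_null(x, x, permutations=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 1 / 100

    def test_reversed_order_anticorrelated(self):
        x = np.arange(10.0)
        r, _ = correlation_with_permutation_null(x, x[::-1], permutations=199, seed=1)
        assert r < 0

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r, _ = correlation_with_permutation_null(x, y, permutations=199, seed=0)
        assert r == pytest.approx(stats.pearsonr(x, y).statistic)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=10), rng.normal(size=10)
        a = correlation_with_permutation_null(x, y, permutations=499, seed=3)
        b = correlation_with_permutation_null(x, y, permutations=499, seed=3)
        assert a == b

    def test_type_one_error_near_nominal(self):
        """Under independence the test should reject at ~5%; check the
        empirical rate over repeated null draws against a 99.9% binomial band."""
        rng = np.random.default_rng(12345)
        n_reps, n_pairs, alpha = 400, 10, 0.05
        rejections = 0
        for i in range(n_reps):
            x = rng.normal(size=n_pairs)
            y = rng.normal(size=n_pairs)
            _, p = correlation_with_permutation_null(x, y, permutations=199, seed=i)
            rejections += p <= alpha
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n_reps, alpha)
        assert lo <= rejections <= hi

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlation_with_permutation_null([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlation_with_permutation_null([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            correlation_with_permutation_null(np.arange(5.0), np.arange(5.0), permutations=10)


class TestBetaSensitivitySweep:
    def test_fitted_cell_matches_wildtype(self, ref_params, inputs, calibration, wt_traj):
        b6, b7 = ref_params.beta[5], ref_params.beta[6]
        grid = beta_sensitivity_sweep(
            ref_params, inputs, REFERENCE_X0, calibration, [b6], [b7]
        )
        wt_rl = predict_flowering(wt_traj, calibration).rosette_leaves
        assert grid[0, 0] == pytest.approx(wt_rl, abs=1e-6)

    def test_removing_soc1_activation_delays_flowering(self, ref_params, inputs, calibration):
        b6, b7 = ref_params.beta[5], ref_params.beta[6]
        grid = beta_sensitivity_sweep(
            ref_params, inputs, REFERENCE_X0, calibration, [b6], [0.0, b7]
        )
        assert grid[0, 0] >= grid[0, 1]  # beta7 = 0 flowers no earlier

    def test_flowering_more_sensitive_to_soc1_than_agl24_strength(
        self, ref_params, inputs, calibration
    ):
        """Halving beta7 (SOC1 -> LFY) shifts flowering more than halving
        beta6 (AGL24 -> LFY) near the reference point."""
        b6, b7 = ref_params.beta[5], ref_params.beta[6]
        grid = beta_sensitivity_sweep(
            ref_params, inputs, REFERENCE_X0, calibration,
            [0.5 * b6, b6], [0.5 * b7, b7],
        )
        base = grid[1, 1]
        shift_b6 = grid[0, 1] - base
        shift_b7 = grid[1, 0] - base
        assert shift_b7 > shift_b6 >= 0

    def test_never_crossing_yields_sentinel(self, ref_params, inputs, calibration):
        grid = beta_sensitivity_sweep(
            ref_params, inputs, REFERENCE_X0, calibration, [0.0], [0.0]
        )
        assert grid[0, 0] == NO_FLOWERING
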