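"""Protonation-ensemble free-energy bookkeeping: offsets, weights, entropy, cycle, pKa."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdelquant import synthetic as sy
from kdelquant import thermo as th

CTX298 = th.ThermoContext(298.15)
CTX310 = th.ThermoContext(310.0)


class TestCalibrationOffset:
    def test_reference_ph_gives_zero(self):
        assert th.calibration_offset(th.ReferencePka("HIS", 7.0), CTX310) == 0.0

    def test_histidine_at_298K(self):
        # 2.303 * R * 298.15 * (7.0 - 6.0) = 1.3645 kcal/mol
        off = th.calibration_offset(th.ReferencePka.default("HIS"), CTX298)
        assert off == pytest.approx(1.3645, abs=2e-4)

    def test_lysine_at_310K(self):
        # 2.303 * R * 310 * (7.0 - 8.95) = -2.767 kcal/mol
        off = th.calibration_offset(th.ReferencePka.default("LYS"), CTX310)
        assert off == pytest.approx(-2.767, abs=2e-3)


class TestBoltzmannWeights:
    def test_degenerate_pair_is_half_half(self):
        assert np.allclose(th.boltzmann_weights([0.0, 0.0], CTX310), [0.5, 0.5])

    def test_hand_computed_asymmetric_pair(self):
        # exp(-1.364/RT(298)) ~ 0.100 -> weights ~ [0.909, 0.091]
        w = th.boltzmann_weights([0.0, 1.364], CTX298)
        assert w[0] == pytest.approx(0.909, abs=1e-3)
        assert w[1] == pytest.approx(0.091, abs=1e-3)

    def test_extreme_value_no_overflow(self):
        w = th.boltzmann_weights([0.0, 1000.0], CTX310)
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(0.0, abs=1e-200)

    def test_nan_raises(self):
        with pytest.raises(ValueError):
            th.boltzmann_weights([0.0, float("nan")], CTX310)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weights_normalise_and_positive(self, dgs):
        w = th.boltzmann_weights(dgs, CTX310)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()


class TestEntropy:
    def test_pure_state_zero_entropy(self):
        ds, mtds = th.configurational_entropy([1.0], CTX310)
        assert ds == 0.0 and mtds == 0.0

    def test_two_state_half_half(self):
        # -T dS = -R T ln 2 = -0.4108 kcal/mol at 298.15 K
        _, mtds = th.configurational_entropy([0.5, 0.5], CTX298)
        assert mtds == pytest.approx(-0.4108, abs=2e-4)

    def test_uniform_attains_upper_bound(self):
        ds, _ = th.configurational_entropy([1 / 3] * 3, CTX310)
        assert ds == pytest.approx(th.GAS_CONSTANT_KCAL * math.log(3), rel=1e-12)

    def test_negative_weight_raises(self):
        with pytest.raises(ValueError):
            th.configurational_entropy([1.2, -0.2], CTX310)

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_entropy_bounded_by_uniform(self, dgs):
        w = th.boltzmann_weights(dgs, CTX310)
        ds, _ = th.configurational_entropy(w, CTX310)
        assert -1e-15 <= ds <= th.GAS_CONSTANT_KCAL * math.log(len(dgs)) + 1e-12


class TestEnsembleDeprotonation:
    def test_no_legs_fully_protonated(self):
        ens = th.ensemble_deprotonation([], th.ReferencePka.default("HIS"), CTX310)
        assert ens.ensemble_dg == 0.0
        assert ens.entropy == 0.0
        assert ens.fraction_protonated == 1.0

    def test_degenerate_three_state_histidine(self):
        # legs equal to the offset make all effective dGs zero:
        # uniform weights and ensemble_dg = -T R ln 3
        off = th.calibration_offset(th.ReferencePka.default("HIS"), CTX310)
        legs = [
            th.AlchemicalLeg("HIP2HID", "complex", [off]),
            th.AlchemicalLeg("HIP2HIE", "complex", [off]),
        ]
        ens = th.ensemble_deprotonation(legs, th.ReferencePka.default("HIS"), CTX310)
        assert np.allclose(ens.weights, 1 / 3)
        assert ens.ensemble_dg == pytest.approx(
            -310.0 * th.GAS_CONSTANT_KCAL * math.log(3), rel=1e-12
        )

    def test_large_positive_dg_fully_protonated_limit(self):
        legs = [th.AlchemicalLeg("HIP2HID", "complex", [500.0])]
        ens = th.ensemble_deprotonation(legs, th.ReferencePka.default("HIS"), CTX310)
        assert ens.ensemble_dg == pytest.approx(0.0, abs=1e-10)

    def test_mixed_residue_legs_rejected(self):
        legs = [th.AlchemicalLeg("LYS2LYN", "complex", [1.0])]
        with pytest.raises(ValueError):
            th.ensemble_deprotonation(legs, th.ReferencePka.default("HIS"), CTX310)

    def test_reversed_leg_label_rejected_with_hint(self):
        with pytest.raises(ValueError, match="HIP2HID"):
            th.AlchemicalLeg("HID2HIP", "complex", [1.0])


class TestCycle:
    def test_reduces_to_lys2hip_when_ensembles_trivial(self):
        lys = th.ensemble_deprotonation([], th.ReferencePka.default("LYS"), CTX310)
        hip = th.ensemble_deprotonation([], th.ReferencePka.default("HIS"), CTX310)
        leg = th.AlchemicalLeg("LYS2HIP", "complex", [-3.25])
        res = th.combine_cycle(lys, hip, leg, CTX310)
        assert res.dg_kdel_to_hdel == pytest.approx(-3.25)

    def test_closed_cycle_sums_to_zero(self):
        # identical legs in both environments: ΔΔG_bind must vanish; and the
        # forward cycle plus the reverse (negated-leg) cycle must cancel
        cfg = sy.GeneratorConfig(seed=13, leg_sd=0.0, target_ddg_bind=-1.8)
        legs, _ = sy.gen_alchemical_legs(cfg)
        same_env = legs.copy()
        same_env.loc[same_env.environment == "complex", "dG_kcal_mol"] = (
            same_env.loc[same_env.environment == "solution", "dG_kcal_mol"].to_numpy()
        )
        model = th.ProtonationCycleModel.from_dataframe(same_env)
        res = model.fit(method="quadrature")
        assert abs(res.ddg_bind) < 1e-12

        fwd = th.ProtonationCycleModel.from_dataframe(legs).fit(method="quadrature")
        total = fwd.ddg_bind - cfg.target_ddg_bind
        assert abs(total) < 1e-10

    def test_planted_cycle_recovery_zero_noise(self):
        cfg = sy.GeneratorConfig(seed=1, leg_sd=0.0)
        legs, manifest = sy.gen_alchemical_legs(cfg)
        res = th.ProtonationCycleModel.from_dataframe(legs).fit(method="quadrature")
        assert res.ddg_bind == pytest.approx(
            manifest["planted_ddg_bind_kcal_mol"], abs=1e-10
        )
        assert res.complex_cycle.dg_kdel_to_hdel == pytest.approx(
            manifest["planted_dg_complex_kcal_mol"], abs=1e-10
        )

    def test_noisy_recovery_within_propagated_uncertainty(self):
        cfg = sy.GeneratorConfig(seed=42, leg_sd=0.5)
        legs, manifest = sy.gen_alchemical_legs(cfg)
        res = th.ProtonationCycleModel.from_dataframe(legs).fit(n_mc=2000, seed=0)
        err = abs(res.ddg_bind - manifest["planted_ddg_bind_kcal_mol"])
        assert err < 3 * res.ddg_bind_sd

    def test_missing_required_leg_keyed_error(self):
        with pytest.raises(KeyError, match="LYS2HIP"):
            th.ProtonationCycleModel(
                [th.AlchemicalLeg("LYS2HIP", "complex", [1.0])]
            )

    def test_mc_converges_to_quadrature_in_small_noise_limit(self):
        cfg = sy.GeneratorConfig(seed=3, leg_sd=0.05)
        legs, _ = sy.gen_alchemical_legs(cfg)
        model = th.ProtonationCycleModel.from_dataframe(legs)
        mc = model.fit(n_mc=8000, seed=5)
        quad = model.fit(method="quadrature")
        assert mc.ddg_bind_sd == pytest.approx(quad.ddg_bind_sd, rel=0.1)


class TestRelativeBinding:
    def test_identical_environments_zero(self):
        r = th.CycleResult(-3.0, 0.0, {}, "complex")
        s = th.CycleResult(-3.0, 0.0, {}, "solution")
        assert th.relative_binding_ddg(r, s) == 0.0

    def test_planted_subtraction(self):
        r = th.CycleResult(-3.0, 0.0, {}, "complex")
        s = th.CycleResult(-1.2, 0.0, {}, "solution")
        assert th.relative_binding_ddg(r, s) == pytest.approx(-1.8)


class TestSitePka:
    def test_equal_legs_give_reference_pka(self):
        site = th.AlchemicalLeg("HIP2HID", "complex", [2.0])
        sol = th.AlchemicalLeg("HIP2HID", "solution", [2.0])
        assert th.site_pka(site, sol, th.ReferencePka.default("HIS"), CTX310) == 6.0

    def test_one_unit_shift(self):
        shift = 2.303 * CTX310.rt
        site = th.AlchemicalLeg("HIP2HID", "complex", [2.0 + shift])
        sol = th.AlchemicalLeg("HIP2HID", "solution", [2.0])
        pka = th.site_pka(site, sol, th.ReferencePka.default("HIS"), CTX310)
        assert pka == pytest.approx(7.0, abs=1e-10)

    def test_transformation_mismatch_rejected(self):
        site = th.AlchemicalLeg("HIP2HID", "complex", [1.0])
        sol = th.AlchemicalLeg("HIP2HIE", "solution", [1.0])
        with pytest.raises(ValueError):
            th.site_pka(site, sol, th.ReferencePka.default("HIS"), CTX310)

    def test_planted_pka_recovered_zero_noise(self):
        cfg = sy.GeneratorConfig(seed=6, leg_sd=0.0, target_pka_his=8.9)
        legs, _ = sy.gen_alchemical_legs(cfg)
        res = th.ProtonationCycleModel.from_dataframe(legs).fit(method="quadrature")
        assert res.site_pkas["HIP2HID"] == pytest.approx(8.9, abs=1e-9)
        assert res.site_pkas["HIP2HIE"] == pytest.approx(8.9, abs=1e-9)

    def test_henderson_hasselbalch_midpoint(self):
        assert th.fraction_protonated(8.9, 8.9) == pytest.approx(0.5)
        assert th.fraction_protonated(8.9, 5.4) > 0.99


def test_parameter_recovery_across_seeds():
    """Planted cycle and pKa estimates match plants within propagated error."""
    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        cfg = sy.GeneratorConfig(seed=seed, leg_sd=0.5)
        legs, manifest = sy.gen_alchemical_legs(cfg)
        res = th.ProtonationCycleModel.from_dataframe(legs).fit(method="quadrature")
        if abs(res.ddg_bind - manifest["planted_ddg_bind_kcal_mol"]) <= 2 * res.ddg_bind_sd:
            hits += 1
    # ~95% nominal coverage; allow binomial slack
    assert hits >= int(0.85 * n_seeds)
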