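"""Reduced clock model: repression function, right-hand side structure,
mutant parameterization, total-protein bookkeeping and effective
degradation."""

import math

import numpy as np
import pytest

from segclock import (
    ClockParameters,
    MonomerState,
    effective_degradation,
    make_mutant,
    minimal_rhs,
    repression,
    simulate,
    summarize,
    total_protein,
    total_protein_series,
)
from segclock.dde import Trajectory


class TestRepression:
    def test_no_repressor_gives_full_production(self):
        assert repression(0.0, 0.0, 2.0) == 1.0

    @pytest.mark.parametrize("n", [1.0, 2.0, 3.0, 7.5])
    def test_combined_dimer_level_at_threshold_halves_production(self, n):
        assert repression(0.5, 0.5, n) == pytest.approx(0.5)

    def test_hill_form(self):
        assert repression(10.0, 0.0, 2.0) == pytest.approx(1.0 / 101.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            repression(-0.1, 0.0, 2.0)
        with pytest.raises(ValueError):
            repression(0.0, -1.0, 2.0)


class TestMinimalRhs:
    def test_empty_state_produces_at_full_rate(self):
        p = ClockParameters()
        zero = MonomerState(0.0, 0.0, 0.0)
        assert minimal_rhs(zero, zero, zero, p) == pytest.approx(
            (p.kappa1, p.kappa6, p.kappa7)
        )

    @pytest.mark.parametrize("double_loss,expected", [(False, -4.0), (True, -5.0)])
    def test_pure_decay_with_dimer_mediated_term(self, double_loss, expected):
        # at unit concentrations and delta=1 the per-monomer loss is
        # 1 + 3 (plus one more for the homodimer self term variant)
        p = ClockParameters(kappa1=0.0, kappa6=0.0, kappa7=0.0,
                            homodimer_double_loss=double_loss)
        ones = MonomerState(1.0, 1.0, 1.0)
        assert minimal_rhs(ones, ones, ones, p) == pytest.approx(
            (expected, expected, expected)
        )

    def test_hes6_equation_has_no_delay_or_repression_term(self):
        # dh6/ds depends only on the current state, whatever the delayed
        # states are
        p = ClockParameters()
        now = MonomerState(1.0, 2.0, 3.0)
        rng = np.random.default_rng(0)
        reference = minimal_rhs(now, now, now, p)[1]
        for _ in range(5):
            za = MonomerState(*rng.uniform(0, 5, 3))
            zb = MonomerState(*rng.uniform(0, 5, 3))
            assert minimal_rhs(now, za, zb, p)[1] == reference


class TestMakeMutant:
    def test_single_mutants_zero_one_rate(self, wt_params):
        m7 = make_mutant(wt_params, "her7")
        assert (m7.kappa7, m7.kappa1, m7.kappa6) == (0.0, 10.0, 90.0)
        m6 = make_mutant(wt_params, "hes6")
        assert (m6.kappa6, m6.kappa1, m6.kappa7) == (0.0, 10.0, 10.0)

    def test_wildtype_is_identity(self, wt_params):
        assert make_mutant(wt_params, "wildtype") == wt_params

    def test_double_mutants_zero_both(self, wt_params):
        m = make_mutant(wt_params, "her1;hes6")
        assert (m.kappa1, m.kappa6, m.kappa7) == (0.0, 0.0, 10.0)

    def test_heterozygote_halves_hes6_production(self, wt_params):
        assert make_mutant(wt_params, "hes6_het").kappa6 == 45.0

    def test_unknown_genotype_rejected(self, wt_params):
        with pytest.raises(ValueError, match="unknown genotype"):
            make_mutant(wt_params, "her99")


class TestTotalProtein:
    def test_empty_state(self):
        zero = MonomerState(0.0, 0.0, 0.0)
        for f in ("her1", "her7", "hes6"):
            assert total_protein(zero, f) == 0.0

    def test_monomer_plus_homodimer(self):
        assert total_protein(MonomerState(1.0, 0.0, 0.0), "her1") == 3.0

    def test_all_dimer_channels(self):
        # h6 + 2 h6^2 + h6 h1 + h6 h7 = 1 + 2 + 1 + 1
        assert total_protein(MonomerState(1.0, 1.0, 1.0), "hes6") == 5.0

    def test_series_matches_pointwise_formula(self, wt_traj):
        i = wt_traj.times.size // 2
        state = MonomerState(*wt_traj.states[i])
        series = total_protein_series(wt_traj, "her1")
        assert series[i] == pytest.approx(total_protein(state, "her1"))

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError):
            total_protein(MonomerState(1.0, 1.0, 1.0), "myod")


def _constant_trajectory(state, n=2000, dt=0.1):
    times = dt * np.arange(n)
    states = np.tile(state, (n, 1))
    return Trajectory(times, states, ["h1", "h6", "h7"])


class TestEffectiveDegradation:
    def test_empty_state_has_unit_rate(self):
        traj = _constant_trajectory([0.0, 0.0, 0.0])
        rate, half_life = effective_degradation(traj, ClockParameters())
        assert rate == pytest.approx(1.0)
        assert half_life == pytest.approx(math.log(2.0))

    def test_unit_state_rate(self):
        traj = _constant_trajectory([1.0, 1.0, 1.0])
        rate, half_life = effective_degradation(traj, ClockParameters())
        assert rate == pytest.approx(4.0)
        assert half_life == pytest.approx(math.log(2.0) / 4.0)

    def test_hes6_loss_stabilizes_oscillating_proteins(
        self, wt_traj, hes6_traj, wt_params
    ):
        # without Hes6 the heterodimer loss channel shrinks, so the
        # effective degradation rate drops and the half-life lengthens
        rate_wt, hl_wt = effective_degradation(wt_traj, wt_params)
        p6 = make_mutant(wt_params, "hes6")
        rate_mut, hl_mut = effective_degradation(hes6_traj, p6)
        assert rate_wt > rate_mut
        assert hl_wt < hl_mut


class TestSimulation:
    def test_wildtype_oscillates(self, wt_traj):
        s = summarize(wt_traj)
        assert s.classification == "sustained"
        assert s.period > 0 and s.amplitude > 0

    def test_no_production_decays_to_zero(self):
        p = ClockParameters(kappa1=0.0, kappa6=0.0, kappa7=0.0)
        traj = simulate(p, t_end=50.0)
        assert summarize(traj).classification == "fixed_point"
        assert np.all(traj.states[-1] < 1e-8)

    def test_components_bounded_by_production_rates(self, wt_traj, wt_params):
        # production is bounded by kappa_i and loss is at least linear,
        # so each component stays within [0, kappa_i]
        assert np.all(wt_traj.states >= 0.0)
        for label, kappa in (("h1", wt_params.kappa1),
                             ("h6", wt_params.kappa6),
                             ("h7", wt_params.kappa7)):
            assert np.all(wt_traj.component(label) <= kappa * (1.0 + 1e-9))

    def test_negative_clamp_never_triggers_at_reference_parameters(
        self, wt_traj, hes6_traj
    ):
        assert wt_traj.meta["clamp_events"] == 0
        assert hes6_traj.meta["clamp_events"] == 0

    def test_double_loss_variant_keeps_wildtype_oscillating(self):
        p = ClockParameters(homodimer_double_loss=True)
        assert summarize(simulate(p)).classification == "sustained"


class TestParameterIO:
    def test_yaml_round_trip(self, tmp_path):
        p = ClockParameters(kappa6=45.0, tau1=1.04)
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        assert ClockParameters.from_yaml(path) == p

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("kappa1: 10\nkappa9: 3\n")
        with pytest.raises(ValueError, match="kappa9"):
            ClockParameters.from_yaml(path)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ClockParameters(kappa1=-1.0)
        with pytest.raises(ValueError):
            ClockParameters(n=0.5)
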