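"""Path-integral machinery: closed forms, BQCP sampling, mass FEP, PI KIEs."""

import math

import numpy as np
import pytest

from isokie.pifep import (
    ModelPotential,
    PISettings,
    QuantumCorrection,
    bead_convergence,
    bqcp_quantum_correction,
    classical_free_energy_ho,
    mass_perturbed_difference,
    pi_free_energy_ho_exact,
    pi_kie,
    pi_kie_from_ddg,
    pi_kie_from_frequency_sets,
    quantum_free_energy_ho,
    sample_paths,
)
from isokie.thermo import ThermoSettings
from isokie.vibrations import FrequencySet

TH298 = ThermoSettings(temperature=298.0)
M_H, M_D = 1.00782503, 2.01410178


def exact_df(nu, th, beads):
    """Closed-form P-bead quantum correction of a harmonic mode."""
    return pi_free_energy_ho_exact(nu, th, beads) - classical_free_energy_ho(nu, th)


class TestClosedForms:
    def test_single_bead_is_classical(self):
        assert pi_free_energy_ho_exact(2900.0, TH298, 1) == pytest.approx(
            classical_free_energy_ho(2900.0, TH298), rel=1e-12
        )
        assert classical_free_energy_ho(2900.0, TH298) == pytest.approx(1.563, abs=1e-3)

    def test_large_p_reaches_exact_quantum(self):
        f_inf = quantum_free_energy_ho(2900.0, TH298)
        assert f_inf == pytest.approx(4.146, abs=1e-3)  # ~ zero-point energy
        assert pi_free_energy_ho_exact(2900.0, TH298, 2**14) == pytest.approx(
            f_inf, abs=1e-6
        )

    def test_bead_truncation_errors(self):
        devs = {p: abs(exact_df(2900.0, TH298, p) - (quantum_free_energy_ho(2900.0, TH298) - classical_free_energy_ho(2900.0, TH298)))
                for p in (32, 64)}
        assert devs[64] == pytest.approx(0.008, abs=1e-3)
        assert devs[32] == pytest.approx(0.032, abs=2e-3)

    def test_monotone_convergence_in_bead_count(self):
        values = [pi_free_energy_ho_exact(2900.0, TH298, p) for p in range(2, 1025)]
        assert np.all(np.diff(values) > 0)
        assert values[-1] < quantum_free_energy_ho(2900.0, TH298)


class TestBeadConvergence:
    def test_loose_tolerance_returns_smallest(self):
        conv = bead_convergence(2900.0, TH298, (8, 16, 32, 64), tolerance=1.0)
        assert conv.converged_beads == 8

    def test_stiff_mode_needs_64_beads(self):
        conv = bead_convergence(2900.0, TH298, (8, 16, 32, 64), tolerance=0.02)
        assert conv.converged_beads == 64
        assert list(conv.table["P"]) == [8, 16, 32, 64]

    def test_soft_mode_converges_immediately(self):
        conv = bead_convergence(100.0, TH298, (8, 16, 32, 64), tolerance=0.02)
        assert conv.converged_beads == 8

    def test_none_converged_reports_deviations(self):
        with pytest.raises(ValueError, match="deviations"):
            bead_convergence(2900.0, TH298, (2, 4), tolerance=0.02)


class TestBQCP:
    def test_harmonic_correction_matches_closed_form(self):
        pot = ModelPotential.harmonic_from_wavenumber(2900.0, M_H, M_D)
        s = PISettings(beads=16, temperature=298.0, n_classical=3000,
                       pi_steps_per_config=10, seed=13)
        qc = bqcp_quantum_correction(pot, s)
        assert abs(qc.df_qm - exact_df(2900.0, TH298, 16)) < 3 * qc.se

    def test_classical_limit_high_temperature(self):
        pot = ModelPotential.harmonic_from_wavenumber(500.0, M_H, M_D)
        s = PISettings(beads=16, temperature=1e6, n_classical=500, seed=2)
        qc = bqcp_quantum_correction(pot, s)
        assert abs(qc.df_qm) < 1e-3

    def test_heavy_mass_limit_vanishes(self):
        # same force constant, mass ×1e6: an ħ→0 surrogate
        base = ModelPotential.harmonic_from_wavenumber(2900.0, M_H, M_D)
        pot = ModelPotential(form="harmonic", params=base.params,
                             mass_light=M_H * 1e6, mass_heavy=M_D * 1e6)
        s = PISettings(beads=16, temperature=298.0, n_classical=500, seed=2)
        qc = bqcp_quantum_correction(pot, s)
        assert abs(qc.df_qm) < 1e-3

    def test_non_power_of_two_beads_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            PISettings(beads=12)

    def test_too_few_configs_for_jackknife_rejected(self):
        pot = ModelPotential.harmonic_from_wavenumber(2900.0, M_H, M_D)
        s = PISettings(beads=8, n_classical=5, seed=1)
        with pytest.raises(ValueError, match="jackknife"):
            bqcp_quantum_correction(pot, s)

    def test_seeded_paths_deterministic(self):
        pot = ModelPotential.harmonic_from_wavenumber(1500.0, M_H, M_D)
        s = PISettings(beads=8, n_classical=50, seed=42)
        a = sample_paths(pot, s)
        b = sample_paths(pot, s)
        np.testing.assert_array_equal(a.displacements, b.displacements)
        np.testing.assert_array_equal(a.x_classical, b.x_classical)


class TestMassPerturbation:
    def test_unit_ratio_is_exactly_zero(self):
        pot = ModelPotential.harmonic_from_wavenumber(2900.0, M_H, M_H)
        paths = sample_paths(pot, PISettings(beads=8, n_classical=100, seed=1))
        diff, se = mass_perturbed_difference(paths, 1.0)
        assert diff == 0.0 and se == 0.0

    def test_h_to_d_matches_closed_form(self):
        ratio = M_D / M_H
        pot = ModelPotential.harmonic_from_wavenumber(2900.0, M_H, M_D)
        paths = sample_paths(pot, PISettings(beads=32, n_classical=4000,
                                             temperature=298.0, seed=5))
        diff, se = mass_perturbed_difference(paths, ratio)
        expected = exact_df(2900.0 / math.sqrt(ratio), TH298, 32) - exact_df(2900.0, TH298, 32)
        assert abs(diff - expected) < 3 * se

    def test_carbon_shift_much_smaller_than_hydrogen(self):
        th = TH298
        pot_h = ModelPotential.harmonic_from_wavenumber(2900.0, M_H, M_D)
        paths_h = sample_paths(pot_h, PISettings(beads=32, n_classical=2000,
                                                 temperature=298.0, seed=6))
        d_h, _ = mass_perturbed_difference(paths_h, M_D / M_H)
        pot_c = ModelPotential.harmonic_from_wavenumber(1000.0, 12.0, 13.00335484)
        paths_c = sample_paths(pot_c, PISettings(beads=32, n_classical=2000,
                                                 temperature=298.0, seed=6))
        d_c, _ = mass_perturbed_difference(paths_c, 13.00335484 / 12.0)
        # heavy-atom substitution: order 0.05 kcal/mol vs ~1 kcal/mol for H/D
        assert abs(d_c) < 0.1
        assert abs(d_h) > 0.5

    def test_ratio_below_one_rejected(self):
        pot = ModelPotential.harmonic_from_wavenumber(2900.0, M_H, M_D)
        paths = sample_paths(pot, PISettings(beads=8, n_classical=100, seed=1))
        with pytest.raises(ValueError):
            mass_perturbed_difference(paths, 0.5)


def qc(species, iso, df, se=0.01, beads=32, t=298.0):
    return QuantumCorrection(species=species, isotopolog=iso, df_qm=df,
                             se=se, beads=beads, temperature=t)


class TestPIKIE:
    def test_zero_corrections_unity(self):
        th = TH298
        rec = pi_kie(
            (qc("reactant", "light", 0.0), qc("reactant", "heavy", 0.0)),
            (qc("ts", "light", 0.0), qc("ts", "heavy", 0.0)),
            th,
        )
        assert rec.value == pytest.approx(1.0)
        assert rec.provenance == "pi"

    def test_printed_activation_corrections(self):
        # ΔΔG_qm = −3.1 (H) and −2.0 (D) kcal/mol at 298 K
        assert pi_kie_from_ddg(-3.1, -2.0, TH298) == pytest.approx(6.41, abs=0.02)

    def test_swap_isotopologs_gives_reciprocal(self):
        th = TH298
        fwd = pi_kie(
            (qc("reactant", "light", 2.6), qc("reactant", "heavy", 1.9)),
            (qc("ts", "light", 1.1), qc("ts", "heavy", 0.9)),
            th,
        ).value
        assert pi_kie_from_ddg(
            ddg_light=(0.9 - 1.9), ddg_heavy=(1.1 - 2.6), th=th
        ) == pytest.approx(1.0 / fwd, rel=1e-12)

    def test_mismatched_beads_rejected(self):
        with pytest.raises(ValueError, match="bead"):
            pi_kie(
                (qc("reactant", "light", 0.0, beads=16), qc("reactant", "heavy", 0.0)),
                (qc("ts", "light", 0.0), qc("ts", "heavy", 0.0)),
                TH298,
            )

    def test_heavier_isotope_has_smaller_correction(self):
        for nu, m_l, m_h in ((2900.0, M_H, M_D), (1000.0, 12.0, 13.00335484)):
            pot = ModelPotential.harmonic_from_wavenumber(nu, m_l, m_h)
            s_l = PISettings(beads=32, n_classical=1500, temperature=298.0, seed=3)
            light = bqcp_quantum_correction(pot, s_l, isotopolog="light")
            heavy = bqcp_quantum_correction(pot, s_l, isotopolog="heavy")
            assert light.df_qm > 0 and heavy.df_qm > 0
            assert abs(heavy.df_qm) < abs(light.df_qm)

    def test_lost_mode_toy_reaches_bigeleisen_zpe_limit(self):
        """PI KIE for a mode lost at the TS approaches the exact harmonic value."""
        nu_l, nu_h = 2000.0, 2000.0 / math.sqrt(M_D / M_H)
        r_l = FrequencySet(real=np.array([nu_l]))
        r_h = FrequencySet(real=np.array([nu_h]))
        t_l = FrequencySet(real=np.array([]), imaginary=800.0)
        t_h = FrequencySet(real=np.array([]), imaginary=800.0)
        settings = PISettings(beads=64, n_classical=3000, temperature=298.0, seed=9)
        rec = pi_kie_from_frequency_sets(r_l, r_h, t_l, t_h, settings,
                                         include_classical_factor=False)
        th = ThermoSettings(temperature=298.0)
        expected = math.exp(
            th.beta * (exact_df(nu_l, th, 64) - exact_df(nu_h, th, 64))
        )
        assert abs(rec.value - expected) < 3 * rec.se
        assert rec.value > 1.0
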