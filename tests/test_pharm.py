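"""Competitive occupancy, operational response, thresholds, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromoswitch.pharm import (
    IsomerPharmacology,
    OccupancyState,
    action_spectrum_model,
    analytic_response_ec50,
    classify_switch,
    competitive_occupancy,
    dose_response,
    fdr,
    get_preset,
    independence_threshold,
    plateau_response,
    response,
)
from chromoswitch.photochem import PssCurve


def make_pharm(**kw):
    base = dict(kd_E=1e-8, kd_Z=1e-8, eff_E=-0.3, eff_Z=1.0, basal=0.02,
                hill_transduction=1.0, reserve_tau=10.0)
    base.update(kw)
    return IsomerPharmacology(**base)


class TestOccupancy:
    def test_zero_concentration_empty_receptor(self):
        occ = competitive_occupancy(0.0, 0.5, make_pharm())
        assert occ.rho_E == 0.0 and occ.rho_Z == 0.0

    @pytest.mark.parametrize("fz", [0.0, 0.3, 0.95, 1.0])
    def test_equal_kd_total_occupancy_is_langmuir(self, fz):
        """At c = 5 Kd with equal affinities any E/Z mixture occupies
        5/6 of the sites — the near-saturation arithmetic."""
        pharm = make_pharm()
        occ = competitive_occupancy(5 * pharm.kd_Z, fz, pharm)
        assert occ.rho_E + occ.rho_Z == pytest.approx(5.0 / 6.0, rel=1e-12)

    def test_pure_z_reduces_to_single_ligand_langmuir(self):
        pharm = make_pharm()
        c = 3.7e-8
        occ = competitive_occupancy(c, 1.0, pharm)
        assert occ.rho_Z == pytest.approx(c / (c + pharm.kd_Z), rel=1e-12)
        assert occ.rho_E == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            competitive_occupancy(-1e-9, 0.5, make_pharm())
        with pytest.raises(ValueError):
            competitive_occupancy(1e-9, 1.5, make_pharm())

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        log_c=st.floats(-12.0, -5.0),
        fz=st.floats(0.0, 1.0),
        log_kdE=st.floats(-10.0, -6.0),
        log_kdZ=st.floats(-10.0, -6.0),
    )
    def test_occupancy_conservation(self, log_c, fz, log_kdE, log_kdZ):
        """Property: rho_E + rho_Z + rho_free = 1 exactly, all in [0, 1]."""
        pharm = make_pharm(kd_E=10.0**log_kdE, kd_Z=10.0**log_kdZ)
        occ = competitive_occupancy(10.0**log_c, fz, pharm)
        assert occ.rho_E + occ.rho_Z + occ.rho_free == pytest.approx(1.0, abs=1e-15)
        assert 0.0 <= occ.rho_E <= 1.0 and 0.0 <= occ.rho_Z <= 1.0


class TestResponse:
    def test_empty_receptor_no_basal_gives_zero(self):
        pharm = make_pharm(basal=0.0)
        assert response(OccupancyState(0.0, 0.0), pharm) == 0.0

    def test_inverse_agonist_suppresses_constitutive_activity(self):
        pharm = make_pharm()
        e_base = response(OccupancyState(0.0, 0.0), pharm)
        e_inverse = plateau_response(pharm, 0.0)  # pure E at saturation
        assert e_inverse < e_base

    def test_off_pss_near_compound_free_baseline(self, spectra, phot, trpc4_azpico):
        """At the 440-nm PSS and 10 nM the effect sits within 2% of system
        max of the zero-compound baseline (full photoswitch-off)."""
        from chromoswitch.photochem import compute_pss

        phi = compute_pss(spectra, phot, 440.0)
        e_off = response(competitive_occupancy(1e-8, phi, trpc4_azpico), trpc4_azpico)
        e_base = response(OccupancyState(0.0, 0.0), trpc4_azpico)
        assert abs(e_off - e_base) < 0.02

    def test_brute_force_transduction_oracle(self):
        """E* equals direct evaluation of the composed closed form on 1,000
        random parameter draws."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            pharm = make_pharm(
                kd_E=10 ** rng.uniform(-9, -6),
                kd_Z=10 ** rng.uniform(-9, -6),
                eff_E=rng.uniform(-1, 1),
                eff_Z=rng.uniform(-1, 1),
                basal=rng.uniform(0, 0.5),
                reserve_tau=10 ** rng.uniform(-1, 2),
                hill_transduction=rng.uniform(1, 3),
            )
            c, fz = 10 ** rng.uniform(-11, -5), rng.uniform(0, 1)
            occ = competitive_occupancy(c, fz, pharm)
            # independent composition of the same model, written out longhand
            xZ, xE = fz * c / pharm.kd_Z, (1 - fz) * c / pharm.kd_E
            rZ, rE = xZ / (1 + xZ + xE), xE / (1 + xZ + xE)
            S = (
                pharm.basal * (1 - rZ - rE)
                + max(pharm.basal + pharm.eff_Z, 0) * rZ
                + max(pharm.basal + pharm.eff_E, 0) * rE
            )
            ts = (pharm.reserve_tau * S) ** pharm.hill_transduction
            expected = ts / (ts + 1)
            assert response(occ, pharm) == pytest.approx(expected, rel=1e-10)

    def test_reserve_halved_occupancy_ratio(self):
        """With tau = 10, saturating pure agonist vs half that occupancy
        gives the ratio the transduction formula dictates."""
        pharm = make_pharm(basal=0.0)
        e_full = response(OccupancyState(0.0, 1.0), pharm)
        e_half = response(OccupancyState(0.0, 0.5), pharm)
        assert e_full / e_half == pytest.approx((10.0 / 11.0) / (5.0 / 6.0), rel=1e-12)


class TestDoseResponse:
    def test_preset_half_maximal_at_printed_potency(self, spectra, phot, trpc4_azpico):
        """At the 365-nm PSS the TRPC4 preset is half-maximal at 3.0 nM."""
        from chromoswitch.photochem import compute_pss

        phi = compute_pss(spectra, phot, 365.0)
        ec50 = analytic_response_ec50(trpc4_azpico, phi)
        assert ec50 == pytest.approx(3.0e-9, rel=0.02)
        # the half-effect level really is attained there
        ds = dose_response(trpc4_azpico, phi, np.geomspace(1e-13, 1e-4, 200))
        y = ds.table["response"].to_numpy()
        half = 0.5 * (y[0] + y[-1])
        c_half = 10 ** np.interp(half, y, np.log10(ds.table["conc_M"]))
        assert c_half == pytest.approx(ec50, rel=1e-3)

    def test_silent_e_binder_gives_flat_curve(self):
        pharm = make_pharm(eff_E=0.0)
        ds = dose_response(pharm, 0.0, np.geomspace(1e-12, 1e-5, 20))
        assert np.ptp(ds.table["response"].to_numpy()) < 1e-12

    def test_monotone_when_net_efficacy_single_signed(self, trpc4_azpico):
        ds = dose_response(trpc4_azpico, 0.95, np.geomspace(1e-12, 1e-5, 50))
        assert np.all(np.diff(ds.table["response"].to_numpy()) > 0)

    def test_empty_grid_rejected(self, trpc4_azpico):
        with pytest.raises(ValueError):
            dose_response(trpc4_azpico, 0.5, np.array([]))


class TestFdrAndThreshold:
    def test_identical_pss_gives_zero_fdr(self, trpc4_azpico):
        assert fdr(trpc4_azpico, 0.6, 0.6, 1e-8) == 0.0

    def test_affinity_switch_fdr_collapse_at_high_concentration(self, affinity_ref):
        """20% residual Z at c = 100 Kd occupies 20/21 of sites, so the
        off state nearly saturates and the FDR collapses (Langmuir)."""
        c = 100 * affinity_ref.kd_Z
        occ_off = competitive_occupancy(c, 0.20, affinity_ref)
        assert occ_off.rho_Z == pytest.approx(20.0 / 21.0, rel=1e-12)
        window = fdr(affinity_ref, 0.95, 0.20, c)
        # compare with the Langmuir-predicted plateau difference
        e_on = response(competitive_occupancy(c, 0.95, affinity_ref), affinity_ref)
        e_off = response(occ_off, affinity_ref)
        assert window == pytest.approx(e_on - e_off, abs=1e-15)
        assert abs(window) < 0.01

    def test_efficacy_switch_fdr_concentration_independent(self, trpc4_azpico):
        """Above threshold the on/off window is flat within 5% of max over
        a 100-fold concentration span."""
        th = independence_threshold(trpc4_azpico)
        values = [
            fdr(trpc4_azpico, 0.95, 0.02, c)
            for c in np.geomspace(th.c_min, 100 * th.c_min, 25)
        ]
        assert np.ptp(values) < 0.05

    def test_default_criterion_yields_five_kd_multiples(self, trpc4_azpico):
        th = independence_threshold(trpc4_azpico)
        assert th.multiple == 5
        assert th.multiple_continuous == pytest.approx(0.83 / 0.17, rel=1e-12)

    def test_half_saturation_criterion_yields_one(self, trpc4_azpico):
        assert independence_threshold(trpc4_azpico, tolerance=0.5).multiple == 1

    def test_tolerance_bounds_enforced(self, trpc4_azpico):
        with pytest.raises(ValueError):
            independence_threshold(trpc4_azpico, tolerance=1.2)

    def test_unequal_affinities_warn_and_use_weaker(self):
        pharm = make_pharm(kd_E=1e-7, kd_Z=1e-8)
        with pytest.warns(UserWarning, match="weaker"):
            th = independence_threshold(pharm)
        assert th.kd_used == 1e-7


class TestChromocontrolPlateaus:
    def test_plateau_depends_only_on_pss(self, trpc4_azpico):
        """Equal-affinity switch: the high-c limit of E* is set by phi alone
        (difference < 1e-4 between c = 1e4 Kd and 1e6 Kd)."""
        kd = trpc4_azpico.kd_Z
        for phi in (0.02, 0.5, 0.95):
            e4 = response(competitive_occupancy(1e4 * kd, phi, trpc4_azpico), trpc4_azpico)
            e6 = response(competitive_occupancy(1e6 * kd, phi, trpc4_azpico), trpc4_azpico)
            assert abs(e4 - e6) < 1e-4

    def test_wavelength_rheostat_monotonicity(self, spectra, phot, trpc4_azpico):
        """Plateau effect is ordered 360 nm (strong) > 385 nm (weak) >
        440 nm (off): three light-set activity levels."""
        from chromoswitch.photochem import compute_pss

        levels = [
            plateau_response(trpc4_azpico, compute_pss(spectra, phot, lam))
            for lam in (360.0, 385.0, 440.0)
        ]
        assert levels[0] > levels[1] > levels[2]
        # monotone in phi generally
        phis = np.linspace(0.01, 0.99, 30)
        plateaus = [plateau_response(trpc4_azpico, p) for p in phis]
        assert np.all(np.diff(plateaus) > 0)

    def test_affinity_doubling_defeats_switch_off(self, trpc4_azpico, affinity_ref):
        """Doubling concentration at the off-PSS pushes an affinity switch
        above the on/off midpoint, while the efficacy switch moves < 1%."""
        c = 2 * affinity_ref.kd_Z
        e_on = response(competitive_occupancy(c, 0.95, affinity_ref), affinity_ref)
        e_off = response(competitive_occupancy(c, 0.20, affinity_ref), affinity_ref)
        e_off_2c = response(competitive_occupancy(2 * c, 0.20, affinity_ref), affinity_ref)
        assert e_off_2c > 0.5 * (e_on + e_off)

        th = independence_threshold(trpc4_azpico)
        e1 = response(competitive_occupancy(th.c_min, 0.02, trpc4_azpico), trpc4_azpico)
        e2 = response(competitive_occupancy(2 * th.c_min, 0.02, trpc4_azpico), trpc4_azpico)
        assert abs(e2 - e1) < 0.01


class TestActionSpectrumModels:
    def test_balanced_pss_prediction_is_offset(self):
        pss = PssCurve(np.array([400.0, 450.0]), np.array([0.5, 0.5]))
        pred = action_spectrum_model(pss, "efficacy", 1e-8, scale=2.0, offset=0.7)
        assert pred == pytest.approx([0.7, 0.7])

    def test_concentration_shift_algebra(self, default_pss):
        """Efficacy predictions ignore c_tot; affinity predictions shift by
        exactly scale * log10(2) on doubling."""
        b = -0.3
        eff1 = action_spectrum_model(default_pss, "efficacy", 1e-8, scale=b)
        eff2 = action_spectrum_model(default_pss, "efficacy", 2e-8, scale=b)
        assert np.array_equal(eff1, eff2)
        aff1 = action_spectrum_model(default_pss, "affinity", 1e-8, scale=b)
        aff2 = action_spectrum_model(default_pss, "affinity", 2e-8, scale=b)
        np.testing.assert_allclose(aff2 - aff1, -b * np.log10(2.0), rtol=1e-12)

    def test_degenerate_pss_clamped_with_warning(self):
        pss = PssCurve(np.array([300.0, 400.0, 500.0]), np.array([0.0, 0.5, 1.0]))
        with pytest.warns(UserWarning, match="clamped"):
            pred = action_spectrum_model(pss, "efficacy", 1e-8)
        assert np.all(np.isfinite(pred))

    def test_calibrated_bands_peak_on_360_off_in_400_480(self, spectra, phot):
        """Model-predicted activation is maximal near 360 nm; the best
        switch-off wavelength lies inside the broad 400-480 nm band."""
        from chromoswitch.photochem import pss_curve

        grid = np.arange(330.0, 501.0, 5.0)
        curve = pss_curve(spectra, phot, grid)
        act = action_spectrum_model(curve, "efficacy", 1e-8, scale=-0.3, offset=0.5)
        lam_on = grid[np.argmax(act)]
        lam_off = grid[np.argmin(act)]
        assert 340.0 <= lam_on <= 370.0
        assert 400.0 <= lam_off <= 480.0


class TestClassification:
    def test_nanomolar_opposing_efficacies_are_ideal(self):
        pharm = make_pharm(kd_E=3e-9, kd_Z=3e-9)
        assert classify_switch(pharm).label == "ideal_efficacy"

    def test_bundled_presets_classify_as_documented(self):
        assert classify_switch(get_preset("trpc4_azpico")).label == "ideal_efficacy"
        assert classify_switch(get_preset("ideal_affinity_reference")).label == "affinity"
        assert classify_switch(get_preset("trpc4_azhc_inactive")).label == "inactive"

    def test_z_only_binder_is_affinity_switch(self):
        pharm = make_pharm(kd_E=1e-6, kd_Z=1e-8, eff_E=0.0)
        assert classify_switch(pharm).label == "affinity"

    def test_micromolar_potency_fails_the_ceiling(self):
        pharm = make_pharm(kd_E=3e-6, kd_Z=3e-6)
        sw = classify_switch(pharm)
        assert sw.label == "nonideal_efficacy"
        assert not sw.potency_ok


def test_invalid_pharm_parameters_rejected():
    with pytest.raises(ValueError):
        make_pharm(kd_Z=-1e-9)
    with pytest.raises(ValueError):
        make_pharm(eff_Z=1.5)
    with pytest.raises(ValueError):
        make_pharm(reserve_tau=0.0)


def test_occupancy_state_invariants():
    with pytest.raises(ValueError):
        OccupancyState(0.7, 0.7)
    with pytest.raises(ValueError):
        OccupancyState(-0.1, 0.2)
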