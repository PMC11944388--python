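import dataclasses

import numpy as np
import pytest

from pbbm import (
    FormulationSpec,
    GIPhysiology,
    build_gi_grid,
    extrapolate_peff,
    simulate_oral,
    steady_state_water,
)


def test_peff_reproduces_tabulated_value(drug):
    """Caco-2 0.9e-6 cm/s with RBN=5 extrapolates to 1.57e-1 cm/h (3 s.f.)."""
    peff = extrapolate_peff(0.9e-6 * 3600.0, 5)
    assert peff == pytest.approx(0.157, abs=0.0005)
    assert drug.peff == pytest.approx(peff)


class TestGIGrid:
    def test_midpoint_radii_and_ka(self, physiology):
        grid = build_gi_grid(physiology, 0.157)
        assert grid.radii_cm[0] == pytest.approx(1.75 - 0.75 * 0.5 / 7, rel=1e-12)
        assert grid.radii_cm[-1] == pytest.approx(1.75 - 0.75 * 6.5 / 7, rel=1e-12)
        np.testing.assert_allclose(grid.ka, 2 * 0.157 / grid.radii_cm)
        assert grid.ka[0] == pytest.approx(0.185, abs=0.001)
        assert grid.ka[-1] == pytest.approx(0.298, abs=0.001)

    def test_uniform_radius_gives_uniform_ka(self):
        phys = GIPhysiology(radius_proximal=1.0, radius_distal=1.0)
        grid = build_gi_grid(phys, 0.2)
        np.testing.assert_allclose(grid.ka, 0.4)

    def test_ka_linear_in_peff(self, physiology):
        g1 = build_gi_grid(physiology, 0.1)
        g2 = build_gi_grid(physiology, 0.2)
        np.testing.assert_allclose(g2.ka, 2 * g1.ka)


def _closed_form_fabs(physiology, peff):
    """Independent oracle: fraction absorbed for fully dissolved drug is
    1 - prod_i kT/(kT + ka_i) when water dynamics play no role."""
    grid = build_gi_grid(physiology, peff)
    return 1.0 - np.prod(grid.kt / (grid.kt + grid.ka))


class TestSolutionSimulation:
    def test_oral_bioavailability_matches_closed_form(
        self, oral_solution_2p5, physiology, drug
    ):
        expected = _closed_form_fabs(physiology, drug.peff)
        assert oral_solution_2p5.foral == pytest.approx(expected, abs=0.005)
        assert expected == pytest.approx(0.52, abs=0.005)

    def test_solutions_fully_dissolve(self, oral_solution_2p5):
        assert oral_solution_2p5.fd == pytest.approx(1.0, abs=1e-9)
        assert oral_solution_2p5.fabs == pytest.approx(oral_solution_2p5.foral, rel=1e-9)

    def test_foral_independent_of_dose_and_gastric_emptying(
        self, drug, physiology, disposition, oral_solution_2p5
    ):
        res_dose = simulate_oral(
            drug, FormulationSpec(dose_mg=1.0, form="solution"), physiology, disposition
        )
        assert res_dose.foral == pytest.approx(oral_solution_2p5.foral, rel=1e-6)
        fast_stomach = dataclasses.replace(physiology, gastric_emptying_ks=8.0)
        res_ks = simulate_oral(
            drug, FormulationSpec(dose_mg=2.5, form="solution"), fast_stomach, disposition
        )
        assert res_ks.foral == pytest.approx(oral_solution_2p5.foral, rel=1e-4)

    def test_concentration_linear_in_dose(self, drug, physiology, disposition):
        t = np.arange(0.0, 24.0, 0.25)
        c1 = simulate_oral(
            drug, FormulationSpec(dose_mg=0.5, form="solution"), physiology,
            disposition, times_h=t,
        ).profile.conc_ng_ml
        c5 = simulate_oral(
            drug, FormulationSpec(dose_mg=2.5, form="solution"), physiology,
            disposition, times_h=t,
        ).profile.conc_ng_ml
        np.testing.assert_allclose(c5, 5.0 * c1, rtol=1e-7)


class TestTabletSimulation:
    def test_mass_balance_at_all_output_times(self, oral_tablet_25):
        assert oral_tablet_25.metadata["mass_balance_rel_err_all_times"] < 1e-6
        ledger = oral_tablet_25.mass_ledger
        parts = (
            ledger["gi_solid"] + ledger["gi_dissolved"] + ledger["colon_solid"]
            + ledger["colon_dissolved"] + ledger["central"] + ledger["peripheral"]
            + ledger["eliminated"]
        )
        assert parts == pytest.approx(ledger["dose_mg"], rel=1e-9)

    def test_luminal_concentration_capped_at_solubility(
        self, drug, oral_tablet_25, oral_tablet_2p5
    ):
        cs = drug.solubility_mg_ml
        for res in (oral_tablet_25, oral_tablet_2p5):
            assert res.metadata["max_si_conc_mg_ml"] <= cs * (1 + 2e-3)
            assert res.metadata["max_stomach_conc_mg_ml"] <= cs * (1 + 2e-3)

    def test_bioavailability_split_ordering(self, oral_tablet_2p5, oral_tablet_25):
        for res in (oral_tablet_2p5, oral_tablet_25):
            assert 0.0 < res.foral <= res.fd <= 1.0
            assert res.fabs == pytest.approx(res.foral / res.fd, rel=1e-12)
        # saturation at the high dose depresses the dissolved fraction
        assert oral_tablet_25.fd < oral_tablet_2p5.fd

    def test_fine_particles_converge_to_solution(self, drug, physiology, disposition):
        t = np.arange(0.0, 48.0, 0.1)
        tiny = simulate_oral(
            drug,
            FormulationSpec(dose_mg=2.5, form="ir_tablet", granulation="dry", d90_um=1.0),
            physiology, disposition, times_h=t, z=31.0,
        )
        sol = simulate_oral(
            drug, FormulationSpec(dose_mg=2.5, form="solution"), physiology,
            disposition, times_h=t,
        )
        assert tiny.foral == pytest.approx(sol.foral, rel=0.01)
        assert max(tiny.profile.conc_ng_ml) == pytest.approx(
            max(sol.profile.conc_ng_ml), rel=0.01
        )

    def test_exposure_monotone_in_particle_size(self, drug, physiology, disposition):
        t = np.arange(0.0, 72.0, 0.05)
        results = [
            simulate_oral(
                drug,
                FormulationSpec(dose_mg=5.0, form="ir_tablet", granulation="dry", d90_um=s),
                physiology, disposition, times_h=t, z=31.0,
            )
            for s in (25.0, 83.0, 210.0)
        ]
        cmax = [r.profile.conc_ng_ml.max() for r in results]
        tmax = [r.profile.times_h[r.profile.conc_ng_ml.argmax()] for r in results]
        foral = [r.foral for r in results]
        assert cmax[0] > cmax[1] > cmax[2]
        assert foral[0] > foral[1] > foral[2]
        assert tmax[0] <= tmax[1] <= tmax[2]

    def test_tablet_requires_z(self, drug, physiology, disposition):
        with pytest.raises(ValueError, match="Z"):
            simulate_oral(
                drug,
                FormulationSpec(dose_mg=5.0, form="ir_tablet", granulation="dry", d90_um=83.0),
                physiology, disposition,
            )


def test_steady_state_water_solves_balance(physiology):
    stomach, si = steady_state_water(physiology)
    kt = physiology.si_transit_kt
    kh = physiology.water_reabsorption_kh2o
    # compartment 1 balance: inflow = outflow + reabsorption
    inflow1 = physiology.secretion_r1 + physiology.secretion_r2
    assert inflow1 == pytest.approx((kt + kh) * si[0], rel=1e-12)
    assert stomach == pytest.approx(physiology.secretion_r1 / physiology.gastric_emptying_ks)
    assert np.all(np.diff(si) < 0)  # volumes taper distally
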