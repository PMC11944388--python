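import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbbm import (
    DissolutionCondition,
    ZModelParams,
    classify_dissolution,
    compute_z,
    fit_z_model,
    gen_dissolution_dataset,
    simulate_dissolution,
)
from pbbm.dissolution import (
    dissolution_rate_coefficient,
    frame_to_profiles,
    profiles_to_frame,
)

PARAMS = ZModelParams(z_wet=44.8, dz_dry=8.6, dz_hcl=-22.5)


@pytest.mark.parametrize(
    "granulation,medium,expected",
    [
        ("wet", "ph68_sds", 44.8),
        ("dry", "ph68_sds", 53.4),
        ("wet", "hcl_01n", 22.3),
        ("dry", "hcl_01n", 30.9),
    ],
)
def test_z_covariate_model(granulation, medium, expected):
    assert compute_z(granulation, medium, PARAMS) == pytest.approx(expected)


def test_z_nonpositive_combination_names_offender():
    # wet granulation in HCl would get Z = 10 - 15 < 0; construction must
    # fail and the error must name the offending combination
    with pytest.raises(ValueError, match="wet.*hcl"):
        ZModelParams(z_wet=10.0, dz_dry=10.0, dz_hcl=-15.0)


def _sink_curve(drug, size_cm, z, t_min):
    """Independent first-order oracle: forced-sink limit 100*(1-exp(-k t))."""
    k = z * 3 * drug.diffusion_coeff * drug.solubility_mg_ml / (
        drug.density * drug.diffusion_layer * size_cm
    )
    return 100.0 * (1.0 - np.exp(-k * t_min / 60.0))


def test_forced_sink_limit_matches_first_order_oracle(drug, tablet_factory):
    t = np.array([5.0, 15.0, 30.0, 60.0])
    for d90 in (20.0, 83.0, 160.0):
        prof = simulate_dissolution(
            drug,
            tablet_factory(5.0, d90),
            DissolutionCondition(volume_ml=1e9),
            z=31.0,
            times_min=t,
        )
        expected = _sink_curve(drug, d90 * 1e-4, 31.0, t)
        np.testing.assert_allclose(prof.pct_dissolved, expected, rtol=1e-3)


def test_zero_z_dissolves_nothing(drug, tablet_factory, qc_condition):
    prof = simulate_dissolution(
        drug, tablet_factory(5.0, 83.0), qc_condition, z=0.0,
        times_min=np.array([10.0, 30.0, 60.0]),
    )
    np.testing.assert_allclose(prof.pct_dissolved, 0.0, atol=1e-9)


def test_saturation_caps_dissolved_fraction(drug, tablet_factory):
    """In a small vessel the % dissolved plateaus at 100*Cs*V/dose."""
    cond = DissolutionCondition(volume_ml=50.0)  # capacity 2 mg < 5 mg dose
    prof = simulate_dissolution(
        drug, tablet_factory(5.0, 20.0), cond, z=31.0,
        times_min=np.array([30.0, 120.0, 600.0]),
    )
    cap = 100.0 * drug.solubility_mg_ml * 50.0 / 5.0
    assert prof.pct_dissolved[-1] == pytest.approx(cap, rel=1e-3)
    assert np.all(prof.pct_dissolved <= cap * (1 + 1e-6))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    d90=st.floats(5.0, 500.0),
    z=st.floats(1.0, 60.0),
    dose=st.floats(1.0, 20.0),
)
def test_profile_monotone_in_time_size_and_z(d90, z, dose):
    """Noise-free dissolution is non-decreasing in t, decreasing in size,
    increasing in Z (all else fixed)."""
    from pbbm import apixaban

    drug = apixaban()
    cond = DissolutionCondition(volume_ml=900.0)
    t = np.array([5.0, 10.0, 20.0, 40.0, 60.0])

    def run(d, zz):
        from pbbm import FormulationSpec

        form = FormulationSpec(dose_mg=dose, form="ir_tablet", granulation="dry", d90_um=d)
        return simulate_dissolution(drug, form, cond, z=zz, times_min=t).pct_dissolved

    base = run(d90, z)
    assert np.all(np.diff(base) >= -1e-9)
    assert run(d90 * 1.5, z)[-1] <= base[-1] + 1e-9
    assert run(d90, z * 1.5)[-1] >= base[-1] - 1e-9


def test_classification_thresholds(drug, tablet_factory, qc_condition):
    t = np.arange(5.0, 61.0, 5.0)
    fast = simulate_dissolution(drug, tablet_factory(5.0, 20.0), qc_condition, z=31.0, times_min=t)
    slow = simulate_dissolution(drug, tablet_factory(5.0, 160.0), qc_condition, z=31.0, times_min=t)
    assert classify_dissolution(fast) == "very_fast"
    assert classify_dissolution(slow) == "not_fast"

    from pbbm import DissolutionProfile, FormulationSpec

    flat = DissolutionProfile(
        times_min=np.array([5.0, 15.0, 30.0]),
        pct_dissolved=np.array([100.0, 100.0, 100.0]),
        formulation=FormulationSpec(dose_mg=5.0, form="solution"),
        condition=qc_condition,
    )
    assert classify_dissolution(flat) == "very_fast"
    short = DissolutionProfile(
        times_min=np.array([5.0, 15.0]),
        pct_dissolved=np.array([10.0, 20.0]),
        formulation=FormulationSpec(dose_mg=5.0, form="solution"),
        condition=qc_condition,
    )
    with pytest.raises(ValueError):
        classify_dissolution(short)


def test_profile_frame_round_trip(drug):
    frame = gen_dissolution_dataset(PARAMS, noise_sd=2.0, seed=3)
    profiles = frame_to_profiles(frame)
    back = profiles_to_frame(profiles)
    pd.testing.assert_frame_equal(
        frame.sort_values(["profile_id", "time_min"]).reset_index(drop=True),
        back.sort_values(["profile_id", "time_min"]).reset_index(drop=True),
        check_dtype=False,
    )


class TestZFactorFit:
    def test_zero_noise_recovery(self):
        data = gen_dissolution_dataset(PARAMS, noise_sd=0.0, seed=1)
        fit = fit_z_model(data)
        assert fit.z_wet_ == pytest.approx(44.8, abs=1e-3)
        assert fit.dz_dry_ == pytest.approx(8.6, abs=1e-3)
        assert fit.dz_hcl_ == pytest.approx(-22.5, abs=1e-3)
        assert fit.sigma_ < 1e-4
        assert fit.n_obs_ == 58

    def test_same_seed_bit_identical(self):
        data = gen_dissolution_dataset(PARAMS, noise_sd=2.0, seed=5)
        a = fit_z_model(data, random_state=11)
        b = fit_z_model(data, random_state=11)
        assert (a.z_wet_, a.dz_dry_, a.dz_hcl_, a.neg2_loglik_) == (
            b.z_wet_, b.dz_dry_, b.dz_hcl_, b.neg2_loglik_
        )

    def test_unidentifiable_designs_raise(self):
        data = gen_dissolution_dataset(PARAMS, noise_sd=0.0, seed=1)
        wet_only = data[data["granulation"] == "wet"]
        with pytest.raises(ValueError, match="dz_dry"):
            fit_z_model(wet_only)
        sds_only = data[data["medium"] == "ph68_sds"]
        with pytest.raises(ValueError, match="dz_hcl"):
            fit_z_model(sds_only)

    def test_monte_carlo_recovery_unbiased(self):
        """Across noisy replicates, mean estimates sit within 2 Monte-Carlo SE
        of the generating parameters."""
        truth = {"z_wet_": 44.8, "dz_dry_": 8.6, "dz_hcl_": -22.5}
        n_rep = 24
        estimates = {k: [] for k in truth}
        for s in range(n_rep):
            data = gen_dissolution_dataset(PARAMS, noise_sd=2.0, seed=100 + s)
            fit = fit_z_model(data, random_state=s)
            for k in truth:
                estimates[k].append(getattr(fit, k))
        for k, target in truth.items():
            vals = np.array(estimates[k])
            mc_se = vals.std(ddof=1) / np.sqrt(n_rep)
            assert abs(vals.mean() - target) < 2 * mc_se + 1e-9, (
                f"{k}: mean {vals.mean():.3f} vs {target} (MC SE {mc_se:.3f})"
            )

    def test_gof_table_shape(self):
        data = gen_dissolution_dataset(PARAMS, noise_sd=1.0, seed=2)
        fit = fit_z_model(data)
        assert set(fit.gof_.columns) == {
            "profile_id", "time_min", "observed", "fitted", "residual"
        }
        assert len(fit.gof_) == len(data)
        np.testing.assert_allclose(
            fit.gof_["residual"], fit.gof_["observed"] - fit.gof_["fitted"]
        )


def test_rate_coefficient_rejects_bad_size(drug):
    with pytest.raises(ValueError):
        dissolution_rate_coefficient(drug, 0.0)
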