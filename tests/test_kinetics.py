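import numpy as np
import pytest

from qivivekit.kinetics import (
    ClearanceEstimate,
    EnzymeKinetics,
    FitError,
    ScalingFactors,
    catalytic_efficiency,
    clint_from_depletion,
    fit_michaelis_menten,
    scale_clint,
    scale_vmax,
)
from qivivekit.synthetic import SyntheticSpec, gen_depletion_course, gen_mm_velocities

MM_DESIGN = (0.5, 1, 2, 5, 10, 20, 50, 100)
DEPLETION_DESIGN = (0, 2, 5, 10, 15, 20, 30, 40, 60, 90, 120)


def mm_data(vmax, km, cv=0.0, seed=0, replicates=3):
    return gen_mm_velocities(
        SyntheticSpec(
            kind="mm_velocity",
            true_params={"vmax": vmax, "km": km},
            design=MM_DESIGN,
            replicates=replicates,
            noise_cv=cv,
            seed=seed,
        )
    )


class TestFitMichaelisMenten:
    @pytest.mark.parametrize("vmax,km", [(0.472, 4.31), (0.0786, 16.9)])
    def test_noise_free_recovery(self, vmax, km):
        fit = fit_michaelis_menten(mm_data(vmax, km))
        assert fit.vmax_unscaled == pytest.approx(vmax, rel=1e-3)
        assert fit.km == pytest.approx(km, rel=1e-3)
        assert fit.ce_unscaled == pytest.approx(vmax / km, rel=1e-3)

    def test_noisy_fit_is_nearly_unbiased(self):
        rel_vmax, rel_km = [], []
        for seed in range(100):
            fit = fit_michaelis_menten(mm_data(0.472, 4.31, cv=0.05, seed=seed))
            rel_vmax.append(fit.vmax_unscaled / 0.472 - 1.0)
            rel_km.append(fit.km / 4.31 - 1.0)
        assert abs(np.median(rel_vmax)) < 0.02
        assert abs(np.median(rel_km)) < 0.02

    def test_flat_data_reported(self):
        data = mm_data(0.472, 4.31)
        data.velocities[:] = 0.3
        with pytest.raises(FitError, match="flat"):
            fit_michaelis_menten(data)

    def test_too_few_concentrations_rejected(self):
        data = gen_mm_velocities(
            SyntheticSpec(kind="mm_velocity", true_params={"vmax": 1, "km": 1}, design=(1, 5, 10))
        )
        with pytest.raises(ValueError, match="4 distinct"):
            fit_michaelis_menten(data)

    def test_extrapolated_km_flagged(self):
        # nearly linear data over a range far below Km
        data = gen_mm_velocities(
            SyntheticSpec(
                kind="mm_velocity",
                true_params={"vmax": 10.0, "km": 5000.0},
                design=(0.5, 1, 2, 5, 10),
                replicates=1,
            )
        )
        with pytest.warns(UserWarning, match="extrapolation"):
            fit = fit_michaelis_menten(data)
        assert fit.km_extrapolated

    def test_reports_standard_errors(self):
        fit = fit_michaelis_menten(mm_data(0.472, 4.31, cv=0.05, seed=1))
        assert fit.vmax_se > 0 and fit.km_se > 0


class TestCatalyticEfficiency:
    def test_unscaled_example(self):
        assert catalytic_efficiency(0.472, 4.31) == pytest.approx(0.110, abs=5e-4)

    def test_scaled_example(self):
        assert catalytic_efficiency(11.1, 4.31) == pytest.approx(2.58, abs=5e-3)

    def test_identity(self):
        assert catalytic_efficiency(3.7, 3.7) == 1.0

    @pytest.mark.parametrize("km", [0.0, -1.0])
    def test_nonpositive_km_rejected(self, km):
        with pytest.raises(ValueError):
            catalytic_efficiency(1.0, km)


class TestScaleVmax:
    def test_microsomal_rat(self):
        # 0.472 nmol/min/mg * 46 mg/g * 8.5 g liver -> 11.07 umol/h
        assert scale_vmax(0.472, 46, 8.5) == pytest.approx(11.07, abs=5e-3)
        assert scale_vmax(0.472, 46, 8.5) == pytest.approx(11.1, rel=5e-3)

    def test_s9_rat(self):
        assert scale_vmax(0.799, 165, 8.5) == pytest.approx(67.2, rel=5e-3)

    def test_zero_vmax(self):
        assert scale_vmax(0.0, 46, 8.5) == 0.0

    def test_linearity(self):
        base = scale_vmax(0.3, 46, 8.5)
        assert scale_vmax(0.6, 46, 8.5) == pytest.approx(2 * base, rel=1e-12)
        assert scale_vmax(0.3, 92, 8.5) == pytest.approx(2 * base, rel=1e-12)
        assert scale_vmax(0.3, 46, 17.0) == pytest.approx(2 * base, rel=1e-12)

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(ValueError):
            scale_vmax(0.3, 0.0, 8.5)


def depletion_data(k=0.00192, cv=0.0, seed=0):
    return gen_depletion_course(
        SyntheticSpec(
            kind="depletion",
            true_params={"k": k, "c0": 1.0, "cell_density": 0.5},
            design=DEPLETION_DESIGN,
            noise_cv=cv,
            seed=seed,
        )
    )


class TestClintFromDepletion:
    def test_noise_free_clint(self):
        est = clint_from_depletion(depletion_data())
        assert est.clint_invitro == pytest.approx(0.00384, rel=1e-6)
        assert est.half_life == pytest.approx(np.log(2) / 0.00192, rel=1e-6)

    def test_constant_series_gives_zero(self):
        est = clint_from_depletion(depletion_data(k=0.0))
        assert est.clint_invitro == 0.0
        assert est.flagged_nonpositive_rate
        assert np.isinf(est.half_life)

    def test_noisy_clint_median_bias(self):
        # the shallow depletion (21% over 120 min) makes single-dataset error
        # large (~8% at cv=0.05 by design), but the estimator is unbiased
        errs = []
        for seed in range(100):
            est = clint_from_depletion(depletion_data(cv=0.05, seed=seed))
            errs.append(est.clint_invitro / 0.00384 - 1.0)
        assert abs(np.median(errs)) < 0.03

    def test_increasing_series_warned_not_fatal(self):
        data = depletion_data()
        mask = data.cells_mask
        data.concentrations[mask] = 1.0 + 0.01 * data.times[mask]
        with pytest.warns(UserWarning, match="increases"):
            est = clint_from_depletion(data)
        assert est.clint_invitro == 0.0

    def test_nonpositive_concentrations_dropped(self):
        data = depletion_data()
        data.concentrations[5] = 0.0
        est = clint_from_depletion(data)
        assert est.n_dropped == 1
        assert est.clint_invitro > 0

    def test_too_few_timepoints_rejected(self):
        data = gen_depletion_course(
            SyntheticSpec(kind="depletion", true_params={"k": 0.01, "c0": 1, "cell_density": 0.5}, design=(0, 10, 20))
        )
        with pytest.raises(ValueError, match="4 distinct"):
            clint_from_depletion(data)


class TestScaleClint:
    def test_rat_whole_liver(self):
        # 0.00384 mL/min/1e6 cells * 135000e6 cells/kg * 0.0085 kg -> 0.264 L/h
        assert scale_clint(0.00384, 135_000, 0.0085) == pytest.approx(0.2644, abs=5e-4)

    def test_zero_clint(self):
        assert scale_clint(0.0, 135_000, 0.0085) == 0.0

    def test_linearity_in_liver_mass(self):
        assert scale_clint(0.00384, 135_000, 0.017) == pytest.approx(
            2 * scale_clint(0.00384, 135_000, 0.0085), rel=1e-12
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            scale_clint(-1.0, 135_000, 0.0085)


class TestEnzymeKinetics:
    def test_ce_identities_hold_by_construction(self):
        ek = EnzymeKinetics(vmax_unscaled=0.472, km=4.31).scaled(46, 8.5)
        assert ek.ce_unscaled == ek.vmax_unscaled / ek.km
        assert ek.ce_scaled == ek.vmax_scaled / ek.km

    def test_positive_required(self):
        with pytest.raises(ValueError):
            EnzymeKinetics(vmax_unscaled=-1.0, km=4.31)

    def test_unscaled_ce_requires_scaling_first(self):
        ek = EnzymeKinetics(vmax_unscaled=0.472, km=4.31)
        with pytest.raises(ValueError, match="scaled"):
            _ = ek.ce_scaled


class TestScalingFactors:
    def test_species_defaults(self):
        rat = ScalingFactors.for_species("rat")
        assert (rat.microsomal_protein, rat.s9_protein) == (46.0, 165.0)
        human = ScalingFactors.for_species("human")
        assert (human.microsomal_protein, human.s9_protein) == (40.0, 120.7)

    def test_unknown_species(self):
        with pytest.raises(ValueError):
            ScalingFactors.for_species("mouse")

    def test_unknown_protein_source(self):
        with pytest.raises(ValueError):
            ScalingFactors.for_species("rat").protein_content("cytosol")


def test_clearance_estimate_invariant():
    with pytest.raises(ValueError):
        ClearanceEstimate(clint_invitro=-0.1, depletion_rate=0.1, half_life=1.0)
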