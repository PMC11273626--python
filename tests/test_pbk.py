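import numpy as np
import pytest

from conftest import make_compound, tiny_conversion
from qivivekit.pbk import (
    DoseRegimen,
    N_STATE,
    TISSUES,
    build_pbk,
    extract_cmax,
    local_sensitivity,
    simulate,
)


class TestBuild:
    def test_missing_partition_rejected(self, simple_physiology):
        parent = make_compound("parent", pathways=[tiny_conversion()])
        del parent.partition["fat"]
        with pytest.raises(ValueError, match="fat"):
            build_pbk(simple_physiology, parent, make_compound("met"))

    def test_requires_exactly_one_conversion_pathway(self, simple_physiology):
        parent = make_compound("parent")  # no pathways at all
        with pytest.raises(ValueError, match="exactly one"):
            build_pbk(simple_physiology, parent, make_compound("met"))

    def test_flow_fractions_must_sum_to_one(self, simple_physiology):
        simple_physiology.flow_fractions["fat"] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            build_pbk(
                simple_physiology,
                make_compound("p", pathways=[tiny_conversion()]),
                make_compound("m"),
            )


class TestSimulateBasics:
    def test_zero_dose_is_identically_zero(self, rat_model):
        out = simulate(rat_model, DoseRegimen("oral", 0.0), duration=6.0)
        assert np.all(out.states == 0.0)
        assert extract_cmax(out, "parent", "blood") == 0.0

    def test_inert_iv_bolus_conserves_and_mixes(self, inert_model):
        # all partitions 1, no losses: blood conc settles at dose/total volume
        out = simulate(inert_model, DoseRegimen("iv", 1.0), duration=50.0)
        v_tot = float(np.sum(inert_model._V) + inert_model._Vb)
        expected = out.dose_umol / v_tot
        assert out.blood_conc("parent")[-1] == pytest.approx(expected, rel=1e-6)
        total = np.sum(out.states[1 : 1 + len(TISSUES) + 1], axis=0)
        np.testing.assert_allclose(total, out.dose_umol, rtol=1e-8)

    def test_iv_parent_monotone_after_mixing_metabolite_peaks(self, rat_model):
        out = simulate(rat_model, DoseRegimen("iv", 5.0), duration=12.0)
        blood = out.blood_conc("parent")
        late = blood[out.time > 1.0]
        assert np.all(np.diff(late) <= 1e-12)
        met = out.blood_conc("metabolite")
        peak = np.argmax(met)
        assert 0 < peak < met.size - 1

    def test_unabsorbed_fraction_recorded(self, rat_model):
        out = simulate(rat_model, DoseRegimen("oral", 10.0), duration=2.0)
        assert out.unabsorbed_umol == pytest.approx((1 - rat_model.parent.fa) * out.dose_umol)

    def test_negative_duration_rejected(self, rat_model):
        with pytest.raises(ValueError):
            simulate(rat_model, DoseRegimen("oral", 1.0), duration=-1.0)

    def test_bad_route_rejected(self):
        with pytest.raises(ValueError):
            DoseRegimen("dermal", 1.0)


class TestMassBalance:
    @pytest.mark.parametrize("species", ["rat", "human"])
    @pytest.mark.parametrize("route,dose", [("oral", 1.0), ("oral", 40.0), ("oral", 300.0), ("iv", 5.0)])
    def test_parent_and_metabolite_balance(self, species, route, dose, rat_model, human_model):
        model = rat_model if species == "rat" else human_model
        out = simulate(model, DoseRegimen(route, dose), duration=48.0)
        parent_res, met_res = out.mass_balance_residual()
        assert parent_res < 1e-3
        assert met_res < 1e-3


class TestDoseResponseOfCmax:
    def test_linear_regime_doubling(self, rat_model):
        lo = extract_cmax(simulate(rat_model, DoseRegimen("iv", 0.01), duration=12.0))
        hi = extract_cmax(simulate(rat_model, DoseRegimen("iv", 0.02), duration=12.0))
        assert hi == pytest.approx(2 * lo, rel=0.01)

    def test_cmax_nondecreasing_in_dose(self, rat_model):
        doses = [1.0, 10.0, 40.0, 100.0, 300.0]
        cmax = [
            extract_cmax(simulate(rat_model, DoseRegimen("oral", d), duration=48.0))
            for d in doses
        ]
        assert np.all(np.diff(cmax) > 0)


class TestOneCompartmentOracle:
    def test_bateman_cmax(self, simple_physiology):
        """With instant mixing (huge cardiac output), unit partitions and only
        renal loss, the oral model collapses to the closed-form one-compartment
        solution."""
        physio = simple_physiology
        physio.cardiac_output = 5000.0  # effectively instantaneous distribution
        parent = make_compound("parent", pathways=[tiny_conversion()], ka=0.5, fa=0.8)
        metabolite = make_compound("met", ka=0.0, fa=0.0)
        model = build_pbk(physio, parent, metabolite)

        v_tot = float(np.sum(model._V) + model._Vb)
        cl = physio.gfr_total * parent.fup / parent.bpr
        ke = cl / v_tot
        ka = parent.ka
        dose_umol = model.dose_to_umol(10.0) * parent.fa
        tmax = np.log(ka / ke) / (ka - ke)
        cmax_analytic = (
            dose_umol * ka / (v_tot * (ka - ke)) * (np.exp(-ke * tmax) - np.exp(-ka * tmax))
        )

        out = simulate(model, DoseRegimen("oral", 10.0), duration=48.0)
        cmax = extract_cmax(out, "parent", "blood")
        assert cmax == pytest.approx(cmax_analytic, rel=5e-3)


class TestRK4Equivalence:
    def test_fixed_step_rk4_matches_adaptive(self, rat_model):
        regimen = DoseRegimen("oral", 40.0)
        out = simulate(rat_model, regimen, duration=12.0)
        cmax_adaptive = extract_cmax(out, "parent", "blood")

        y = np.zeros(N_STATE)
        y0, _ = rat_model.initial_state(regimen)
        y[:] = y0
        h = 0.002
        n = int(12.0 / h)
        i_blood = 1 + len(TISSUES)
        best = 0.0
        t = 0.0
        for _ in range(n):
            k1 = rat_model.rhs(t, y)
            k2 = rat_model.rhs(t + h / 2, y + h / 2 * k1)
            k3 = rat_model.rhs(t + h / 2, y + h / 2 * k2)
            k4 = rat_model.rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            best = max(best, y[i_blood] / rat_model._Vb)
        assert best == pytest.approx(cmax_adaptive, rel=5e-3)


class TestExtractCmax:
    def test_monotone_iv_peak_at_first_sample(self, rat_model):
        out = simulate(rat_model, DoseRegimen("iv", 1.0), duration=24.0)
        blood = out.blood_conc("parent")
        assert extract_cmax(out, "parent", "blood") == pytest.approx(np.max(blood), rel=1e-6)

    def test_refinement_stable_under_finer_grid(self, rat_model):
        coarse = simulate(rat_model, DoseRegimen("oral", 40.0), duration=24.0, n_out=200)
        fine = simulate(rat_model, DoseRegimen("oral", 40.0), duration=24.0, n_out=2000)
        for compound in ("parent", "metabolite"):
            a = extract_cmax(coarse, compound, "blood")
            b = extract_cmax(fine, compound, "blood")
            assert a == pytest.approx(b, rel=1e-3)

    def test_tissue_venous_concentration(self, rat_model):
        out = simulate(rat_model, DoseRegimen("oral", 40.0), duration=24.0)
        cmax_liver = extract_cmax(out, "parent", "liver")
        assert cmax_liver > 0
        with pytest.raises(ValueError):
            extract_cmax(out, "parent", "bone")

    def test_unknown_compound(self, rat_model):
        out = simulate(rat_model, DoseRegimen("oral", 1.0), duration=4.0)
        with pytest.raises(ValueError):
            extract_cmax(out, "mystery", "blood")


class TestLocalSensitivity:
    def test_dose_sensitivity_near_one_in_linear_regime(self, rat_model):
        sc = local_sensitivity(rat_model, DoseRegimen("iv", 0.01), "dose", duration=12.0)
        assert sc == pytest.approx(1.0, abs=0.05)

    def test_conversion_vmax_signs(self, rat_model):
        reg = DoseRegimen("oral", 40.0)
        path = "parent.pathways.rhein_formation.vmax_scaled"
        sc_parent = local_sensitivity(rat_model, reg, path, compound="parent", duration=24.0)
        sc_met = local_sensitivity(rat_model, reg, path, compound="metabolite", duration=24.0)
        assert sc_parent < 0
        assert sc_met > 0

    def test_zero_parameter_reported(self, rat_model):
        with pytest.raises(ValueError, match="zero"):
            local_sensitivity(rat_model, DoseRegimen("iv", 1.0), "metabolite.ka", duration=6.0)

    def test_partition_path_resolves(self, rat_model):
        sc = local_sensitivity(
            rat_model, DoseRegimen("oral", 40.0), "parent.partition.slowly", duration=24.0
        )
        assert np.isfinite(sc)
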