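import numpy as np
import pytest

from sippk.ddi import (
    InhibitionSpec,
    NotAtSteadyStateError,
    dynamic_ddi,
    inhibition_factor,
    perpetrator_exposure,
    simulate_victim_inhibited,
    static_aucr,
    time_to_steady_state,
)
from sippk.io import builtin_regimen
from sippk.pk import Regimen, nca, simulate


class TestStaticModel:
    def test_no_inhibitor_is_unity(self, sip):
        assert static_aucr(sip.fm, 0.0, {"CYP2C9": 20.4}) == pytest.approx(1.0)

    def test_infinite_ki_is_unity(self, sip):
        assert static_aucr(sip.fm, 100.0, {"CYP2C9": 1e12, "CYP3A4": 1e12}) == pytest.approx(
            1.0, rel=1e-9
        )

    def test_cyp2c9_only_at_average_fluconazole_exposure(self):
        # ~34 uM average with Ki 20.4 uM doubles exposure of an fm 0.8084 victim
        aucr = static_aucr({"CYP2C9": 0.8084}, 34.0, {"CYP2C9": 20.4})
        assert aucr == pytest.approx(2.0, abs=0.05)

    def test_monotone_in_inhibitor_concentration(self, sip):
        ki = {"CYP2C9": 20.4, "CYP3A4": 10.0}
        values = [static_aucr(sip.fm, i, ki) for i in np.linspace(0, 200, 50)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_bounded_by_uninhibited_fraction(self, sip):
        ki = {"CYP2C9": 20.4, "CYP3A4": 10.0}
        fm_inhibited = sip.fm["CYP2C9"] + sip.fm["CYP3A4"]
        bound = 1.0 / (1.0 - fm_inhibited)
        assert static_aucr(sip.fm, 1e9, ki) <= bound + 1e-9

    def test_invariant_to_splitting_an_enzyme(self):
        ki_one = {"CYP2C9": 20.4}
        ki_two = {"CYP2C9a": 20.4, "CYP2C9b": 20.4}
        a = static_aucr({"CYP2C9": 0.8}, 34.0, ki_one)
        b = static_aucr({"CYP2C9a": 0.5, "CYP2C9b": 0.3}, 34.0, ki_two)
        assert a == pytest.approx(b, rel=1e-12)

    def test_enzymes_without_ki_stay_uninhibited(self, sip):
        only_2c9 = static_aucr(sip.fm, 34.0, {"CYP2C9": 20.4})
        both = static_aucr(sip.fm, 34.0, {"CYP2C9": 20.4, "CYP3A4": 10.0})
        assert both > only_2c9

    def test_negative_concentration_rejected(self, sip):
        with pytest.raises(ValueError):
            inhibition_factor(-1.0, sip.fm, {"CYP2C9": 20.4})


class TestPerpetratorExposure:
    def test_average_matches_mass_balance(self, flu):
        exposure = perpetrator_exposure(flu, Regimen.qd(200, 20))
        css_avg_expected = 200.0 / (flu.cl * 24.0) * 1000.0  # ng/mL
        assert exposure.css_avg_ngml == pytest.approx(css_avg_expected, rel=0.01)
        assert exposure.css_avg_um == pytest.approx(34.0, abs=0.7)
        assert exposure.css_min_um < exposure.css_avg_um < exposure.css_max_um

    def test_short_horizon_raises(self, flu):
        with pytest.raises(NotAtSteadyStateError):
            perpetrator_exposure(flu, Regimen.qd(200, 3))

    def test_loading_dose_reaches_steady_state_earlier(self, flu):
        loaded = builtin_regimen("fluconazole_trial_ii")
        plain = Regimen.qd(200, 21)
        t_loaded = time_to_steady_state(flu, loaded)
        t_plain = time_to_steady_state(flu, plain)
        assert t_loaded < t_plain


class TestDynamicModel:
    def test_constant_inhibitor_matches_static(self, sip, flu):
        i_um = 30.0
        grid = np.arange(0.0, 700.0, 0.5)
        reg = Regimen.single(5.0)
        base = simulate(sip, reg, grid=grid)
        inhibited = simulate_victim_inhibited(sip, reg, lambda t: i_um, flu.ki, grid)
        aucr_dyn = nca(inhibited).auc_inf / nca(base).auc_inf
        assert aucr_dyn == pytest.approx(static_aucr(sip.fm, i_um, flu.ki), rel=5e-3)

    def test_trial_iv_like_cmax_ratio_modest(self, sip, flu):
        result = dynamic_ddi(
            sip,
            flu,
            builtin_regimen("siponimod_trial_iv"),
            builtin_regimen("fluconazole_trial_iv"),
        )
        # absorption untouched; inhibition acts on elimination only
        assert 1.0 < result.cmax_ratio < 1.2
        assert result.cmax_ratio == pytest.approx(1.1, abs=0.1)
        assert result.aucr > 1.5

    def test_half_life_extended_under_sustained_inhibition(self, sip, flu):
        # keep the perpetrator at steady state over the victim's whole tail
        perp = Regimen.qd(200, 40)
        victim = Regimen.single(4.0, 72.0)
        result = dynamic_ddi(sip, flu, victim, perp, t_end=800.0, dt=0.5)
        assert result.t_half_inhibited_h >= result.t_half_base_h
        assert result.t_half_inhibited_h > 1.5 * result.t_half_base_h

    def test_dynamic_aucr_between_static_bounds(self, sip, flu):
        perp = Regimen.qd(200, 50)
        victim = Regimen.single(4.0, 480.0)  # dosed well after perpetrator steady state
        spec = InhibitionSpec.from_perpetrator(flu)
        result = dynamic_ddi(sip, flu, victim, perp, spec, t_end=1150.0, dt=0.5)
        exposure = perpetrator_exposure(flu, perp)
        lo = static_aucr(sip.fm, exposure.css_min_um, spec.ki)
        hi = static_aucr(sip.fm, exposure.css_max_um, spec.ki)
        assert lo - 0.01 <= result.aucr <= hi + 0.01

    def test_no_temporal_overlap_means_no_interaction(self, sip, flu):
        victim = Regimen.single(1.0, 0.0)
        perp = Regimen.qd(200, 5, start_h=400.0)  # after victim washout
        grid = np.arange(0.0, 400.0, 0.5)
        base = simulate(sip, victim, grid=grid)
        from sippk.ddi import _perp_conc_um

        conc_fn = _perp_conc_um(flu, perp, InhibitionSpec.from_perpetrator(flu))
        inhibited = simulate_victim_inhibited(
            sip, victim, conc_fn, flu.ki, grid, breakpoints=perp.times
        )
        assert nca(inhibited).auc_last == pytest.approx(nca(base).auc_last, rel=1e-6)


class TestInhibitionSpec:
    def test_unbound_basis_scales_by_fu(self, flu):
        spec = InhibitionSpec.from_perpetrator(flu, basis="unbound")
        assert spec.effective_um(10.0) == pytest.approx(10.0 * flu.fu)

    @pytest.mark.parametrize("kwargs", [
        {"ki": {"CYP2C9": -1.0}, "mw": 300.0},
        {"ki": {}, "mw": -5.0},
        {"ki": {}, "mw": 300.0, "basis": "plasma-water"},
        {"ki": {}, "mw": 300.0, "metric": "peak-ish"},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InhibitionSpec(**kwargs)
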