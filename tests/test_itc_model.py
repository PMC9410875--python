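"""ITC bookkeeping, simulation, fitting and model selection."""

import numpy as np
import pytest

from foxcoop.itc_model import (
    ONE_SITE,
    TWO_SITE,
    ITCProtocol,
    ThermoParams,
    biphasic_index,
    compare_models,
    concentrations_after_injection,
    dilution_ledger,
    fit_itc,
    simulate_itc,
    wiseman_isotherm,
)
from foxcoop.reference import DEFAULT_ITC_PROTOCOL, P53_ITC_PROTOCOL
from foxcoop.synthetic_data import gen_itc_trace


class TestCellBookkeeping:
    def test_first_injection_displacement_correction(self):
        # 2.5 ul of 750 uM into 200 ul: 750*(2.5/200)*(1 - 2.5/400) uM.
        d, p = concentrations_after_injection(DEFAULT_ITC_PROTOCOL, 0)
        assert p == pytest.approx(9.31640625e-6, rel=1e-12)
        assert d == pytest.approx(50e-6 * (1 - 2.5 / 200), rel=1e-12)

    def test_protein_moles_conserved(self):
        ledger = dilution_ledger(P53_ITC_PROTOCOL)
        gap = np.abs(
            ledger["injected_moles"]
            - ledger["in_cell_moles"]
            - ledger["expelled_moles"]
        )
        assert np.max(gap) < 1e-12 * ledger["injected_moles"][-1]

    def test_injection_index_bounds(self):
        with pytest.raises(ValueError):
            concentrations_after_injection(DEFAULT_ITC_PROTOCOL, 20)

    def test_oversized_injection_rejected(self):
        with pytest.raises(ValueError):
            ITCProtocol(200e-6, 50e-6, 750e-6, (300e-6, 300e-6))


class TestSimulation:
    def test_zero_enthalpy_zero_heat(self):
        params = ThermoParams(TWO_SITE, ka1=1e6, dh1=0.0, ka2=1e5, dh2=0.0)
        trace = simulate_itc(DEFAULT_ITC_PROTOCOL, params)
        assert np.allclose(trace.heats_ucal, 0.0)

    def test_tight_binding_plateau_equals_dh1(self):
        params = ThermoParams(ONE_SITE, ka1=1e12, dh1=-10.0, n=1.0)
        trace = simulate_itc(DEFAULT_ITC_PROTOCOL, params)
        assert trace.normalized_kcal_per_mol[0] == pytest.approx(-10.0, rel=1e-3)

    def test_opposing_enthalpies_give_biphasic_curve(self):
        params = ThermoParams(TWO_SITE, ka1=2.54e6, dh1=-10.0, ka2=1.9e6, dh2=4.0)
        trace = simulate_itc(P53_ITC_PROTOCOL, params)
        q = trace.normalized_kcal_per_mol
        assert np.min(np.diff(q)) < 0 < np.max(np.diff(q))  # non-monotone
        assert biphasic_index(trace) >= 1

    def test_heat_conservation(self):
        params = ThermoParams(TWO_SITE, ka1=2.54e6, dh1=-10.0, ka2=1.9e6, dh2=4.0)
        trace = simulate_itc(DEFAULT_ITC_PROTOCOL, params)
        v0 = DEFAULT_ITC_PROTOCOL.cell_volume
        vols = np.asarray(DEFAULT_ITC_PROTOCOL.injection_volumes)
        q_cum = trace.cumulative_kcal
        q_prev = np.concatenate(([0.0], q_cum[:-1]))
        corrected_total = q_cum[-1] + np.sum((vols / v0) * (q_cum + q_prev) / 2.0)
        total = np.sum(trace.heats_ucal) / 1e9
        assert total == pytest.approx(corrected_total, rel=1e-9)

    def test_agrees_with_wiseman_isotherm_in_no_dilution_limit(self):
        proto = ITCProtocol(
            cell_volume=0.2, cell_conc=50e-6, syringe_conc=1e5,
            injection_volumes=(2e-11,) * 10,
        )
        trace = simulate_itc(proto, ThermoParams(ONE_SITE, ka1=1.27e6, dh1=-10.0))
        ledger = dilution_ledger(proto)
        analytic = wiseman_isotherm(1.27e6, 1.0, -10.0, 0.2, 50e-6, ledger["p_total"])
        rel = np.max(np.abs(trace.cumulative_kcal - analytic)) / np.max(np.abs(analytic))
        assert rel < 1e-8

    def test_two_site_reduces_to_one_site_with_two_sites(self):
        # Ka1 = 2K, Ka2 = K/2 (omega = 1, equal sites) vs one-site n = 2.
        ka = 1.27e6
        two = simulate_itc(
            DEFAULT_ITC_PROTOCOL,
            ThermoParams(TWO_SITE, ka1=2 * ka, dh1=-10.0, ka2=ka / 2, dh2=-10.0),
        )
        one = simulate_itc(
            DEFAULT_ITC_PROTOCOL, ThermoParams(ONE_SITE, ka1=ka, dh1=-10.0, n=2.0)
        )
        assert np.allclose(
            two.normalized_kcal_per_mol, one.normalized_kcal_per_mol, atol=1e-8
        )


class TestFitting:
    def test_one_site_round_trip_at_published_kd(self):
        # KD 0.79 uM -> Ka = 1.27e6 per M, the canonical single-site point.
        truth = ThermoParams(ONE_SITE, ka1=1.27e6, dh1=-10.0, n=1.0)
        trace = simulate_itc(DEFAULT_ITC_PROTOCOL, truth)
        fit = fit_itc(trace, DEFAULT_ITC_PROTOCOL, ONE_SITE)
        assert fit.converged
        assert fit.params.ka1 == pytest.approx(truth.ka1, rel=1e-4)
        assert fit.params.dh1 == pytest.approx(truth.dh1, rel=1e-4)
        assert fit.params.n == pytest.approx(1.0, rel=1e-4)

    def test_two_site_round_trip(self):
        truth = ThermoParams(TWO_SITE, ka1=2.54e6, dh1=-10.0, ka2=1.9e6, dh2=4.0)
        trace = simulate_itc(P53_ITC_PROTOCOL, truth)
        fit = fit_itc(trace, P53_ITC_PROTOCOL, TWO_SITE)
        assert fit.params.ka1 == pytest.approx(truth.ka1, rel=1e-4)
        assert fit.params.ka2 == pytest.approx(truth.ka2, rel=1e-4)
        assert fit.params.dh1 == pytest.approx(truth.dh1, rel=1e-4)
        assert fit.params.dh2 == pytest.approx(truth.dh2, rel=1e-4)

    def test_noisy_recovery_within_stated_power(self):
        # 2% relative heat noise, 25 injections: Ka within 10%, dH within 5%.
        proto = ITCProtocol(200e-6, 50e-6, 750e-6, (2.5e-6,) * 25)
        truth = ThermoParams(ONE_SITE, ka1=1.27e6, dh1=-10.0, n=1.0)
        for seed in (1, 2, 3):
            trace = gen_itc_trace(proto, truth, sigma_heat=0.2, seed=seed)
            fit = fit_itc(trace, proto, ONE_SITE)
            assert fit.params.ka1 == pytest.approx(truth.ka1, rel=0.10)
            assert fit.params.dh1 == pytest.approx(truth.dh1, rel=0.05)

    def test_flat_trace_flagged_unidentifiable(self):
        params = ThermoParams(ONE_SITE, ka1=1e6, dh1=0.0, n=1.0)
        trace = simulate_itc(DEFAULT_ITC_PROTOCOL, params)
        fit = fit_itc(trace, DEFAULT_ITC_PROTOCOL, ONE_SITE)
        assert not fit.converged
        assert "unidentifiable" in fit.message

    def test_too_few_injections_rejected(self):
        proto = ITCProtocol(200e-6, 50e-6, 750e-6, (2.5e-6,) * 4)
        trace = simulate_itc(proto, ThermoParams(ONE_SITE, ka1=1e6, dh1=-5.0))
        with pytest.raises(ValueError, match="8 injections"):
            fit_itc(trace, proto, ONE_SITE)


class TestModelSelection:
    def test_one_site_data_selects_one_site_in_majority_of_runs(self):
        # On single-site data the models differ by at most noise fitting, so
        # the parsimony penalty should win in the clear majority of runs.
        truth = ThermoParams(ONE_SITE, ka1=1.27e6, dh1=-10.0, n=1.0)
        wins = 0
        for seed in range(10):
            trace = gen_itc_trace(DEFAULT_ITC_PROTOCOL, truth, seed=seed)
            wins += compare_models(trace, DEFAULT_ITC_PROTOCOL).selected_model == ONE_SITE
        assert wins >= 7

    def test_biphasic_data_selects_two_site(self):
        truth = ThermoParams(TWO_SITE, ka1=2.54e6, dh1=-10.0, ka2=1.9e6, dh2=4.0)
        trace = gen_itc_trace(P53_ITC_PROTOCOL, truth, seed=5)
        cmp = compare_models(trace, P53_ITC_PROTOCOL)
        assert cmp.selected_model == TWO_SITE
        assert cmp.biphasic_index >= 1
        assert cmp.delta_aicc > 2

    def test_pure_noise_is_indeterminate(self):
        noisy = gen_itc_trace(
            DEFAULT_ITC_PROTOCOL, ThermoParams(ONE_SITE, ka1=1e6, dh1=0.0),
            sigma_heat=0.05, seed=9,
        )
        cmp = compare_models(noisy, DEFAULT_ITC_PROTOCOL)
        assert cmp.indeterminate
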