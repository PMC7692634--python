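"""Thermogram simulation and fitting: bookkeeping, limits, recovery."""

import math

import numpy as np
import pytest

from itcdimer import (
    BindingParameters,
    Thermogram,
    ThermogramFitter,
    TitrationProtocol,
    compare_models,
    fit_thermogram,
    simulate_thermogram,
)
from _oracles import total_heat_with_losses, wiseman_heats


class TestThermogramContainer:
    def test_normalized_heats_definition(self, bench_protocol):
        heats = tuple(float(i + 1) for i in range(bench_protocol.n_injections))
        tg = Thermogram(bench_protocol, heats)
        v = np.asarray(bench_protocol.injection_volumes)
        expected = np.asarray(heats) * 1e-6 / (bench_protocol.syringe_conc * v) / 1e3
        np.testing.assert_allclose(tg.normalized, expected, rtol=1e-12)

    def test_molar_ratio_strictly_increasing(self, bench_protocol):
        tg = Thermogram(bench_protocol, (0.0,) * bench_protocol.n_injections)
        assert np.all(np.diff(tg.molar_ratio) > 0)

    def test_length_mismatch_rejected(self, bench_protocol):
        with pytest.raises(ValueError):
            Thermogram(bench_protocol, (1.0, 2.0))

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            TitrationProtocol(cell_volume=-1, cell_conc=1e-6, syringe_conc=1e-5,
                              injection_volumes=(1e-6, 1e-6))
        with pytest.raises(ValueError):
            TitrationProtocol(cell_volume=1e-3, cell_conc=1e-6, syringe_conc=1e-5,
                              injection_volumes=(1e-6,))


class TestSimulate:
    def test_zero_enthalpies_give_exactly_zero_heat(self, bench_protocol):
        params = BindingParameters(kd1=1e-6, kd2=1e-5, dh1=0.0, dh2=0.0, q_dil=0.0)
        tg = simulate_thermogram(bench_protocol, params)
        assert all(q == 0.0 for q in tg.heats)

    def test_bit_identical_determinism(self, bench_protocol, bench_params):
        a = simulate_thermogram(bench_protocol, bench_params)
        b = simulate_thermogram(bench_protocol, bench_params)
        assert a.heats == b.heats

    @pytest.mark.parametrize("c_value", [1, 10, 100, 1000])
    def test_weak_kd2_limit_matches_wiseman_closed_form(self, bench_protocol, c_value):
        kd = bench_protocol.cell_conc / c_value
        params = BindingParameters(kd1=kd, kd2=1e9, dh1=-8000.0, dh2=0.0)
        sim = np.asarray(simulate_thermogram(bench_protocol, params).heats)
        oracle = np.asarray(wiseman_heats(bench_protocol, kd, -8000.0))
        assert np.max(np.abs(sim - oracle)) <= 1e-6 * np.max(np.abs(oracle))

    def test_biphasic_shape_with_opposed_enthalpies(self, bench_protocol, bench_params):
        nh = simulate_thermogram(bench_protocol, bench_params).normalized
        slope = np.diff(nh)
        assert np.any(slope > 0) and np.any(slope < 0)  # interior extremum

    def test_heat_conservation_against_cumulative_oracle(self, bench_protocol, bench_params):
        """Sum of injection heats equals final binding heat plus the
        perfusion-loss correction, both recomputed by an independent
        2-D bisection speciation path."""
        tg = simulate_thermogram(bench_protocol, bench_params)
        total = sum(tg.heats)
        oracle = total_heat_with_losses(
            bench_protocol, bench_params.kd1, bench_params.kd2,
            bench_params.dh1, bench_params.dh2)
        assert total == pytest.approx(oracle, rel=1e-6)

    def test_dilution_offset_adds_constant(self, bench_protocol):
        base = BindingParameters(kd1=1e-6, kd2=1e-5, dh1=-5000.0, dh2=2000.0, q_dil=0.0)
        offs = BindingParameters(kd1=1e-6, kd2=1e-5, dh1=-5000.0, dh2=2000.0, q_dil=0.7)
        qa = np.asarray(simulate_thermogram(bench_protocol, base).heats)
        qb = np.asarray(simulate_thermogram(bench_protocol, offs).heats)
        np.testing.assert_allclose(qb - qa, 0.7, rtol=0, atol=1e-12)


class TestFit:
    def test_noise_free_double_fit_recovers_truth(self, bench_protocol, bench_params):
        tg = simulate_thermogram(bench_protocol, bench_params)
        res = fit_thermogram(tg, "double_dependent")
        assert res.params.kd1 == pytest.approx(bench_params.kd1, rel=1e-4)
        assert res.params.kd2 == pytest.approx(bench_params.kd2, rel=1e-4)
        assert res.params.dh1 == pytest.approx(bench_params.dh1, rel=1e-4)
        assert res.params.dh2 == pytest.approx(bench_params.dh2, rel=1e-4)
        assert res.rss < 1e-12
        assert len(res.residuals) == bench_protocol.n_injections

    def test_noise_free_single_site_fit_recovers_truth(self, bench_protocol):
        truth = BindingParameters(kd1=5e-6, kd2=1e9, dh1=-9000.0, dh2=0.0, q_dil=0.3)
        tg = simulate_thermogram(bench_protocol, truth)
        res = fit_thermogram(tg, "single_site")
        assert res.params.kd1 == pytest.approx(truth.kd1, rel=1e-4)
        assert res.params.dh1 == pytest.approx(truth.dh1, rel=1e-4)
        assert res.params.q_dil == pytest.approx(truth.q_dil, abs=1e-4)
        assert math.isinf(res.params.kd2)

    def test_too_few_injections_rejected(self):
        proto = TitrationProtocol(cell_volume=1.4e-3, cell_conc=20e-6,
                                  syringe_conc=250e-6, injection_volumes=(8e-6,) * 4)
        tg = Thermogram(proto, (1.0, 1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            fit_thermogram(tg, "double_dependent")

    def test_unknown_scheme_rejected(self, bench_protocol, bench_params):
        tg = simulate_thermogram(bench_protocol, bench_params)
        with pytest.raises(ValueError):
            fit_thermogram(tg, "triple_site")

    def test_exclude_first_drops_one_observation(self, bench_protocol, bench_params):
        tg = simulate_thermogram(bench_protocol, bench_params)
        res_all = fit_thermogram(tg, "double_dependent")
        res_excl = fit_thermogram(tg, "double_dependent", exclude_first=True)
        assert res_excl.n_obs == res_all.n_obs - 1

    def test_sigma_weighting_validation(self, bench_protocol, bench_params):
        tg = simulate_thermogram(bench_protocol, bench_params)
        with pytest.raises(ValueError):
            ThermogramFitter(sigma=[1.0, 2.0]).fit(tg)

    def test_stderr_nonnegative_and_reported(self, bench_protocol, bench_params):
        rng = np.random.default_rng(11)
        heats = np.asarray(simulate_thermogram(bench_protocol, bench_params).heats)
        tg = Thermogram(bench_protocol, tuple(heats + rng.normal(0, 0.5, heats.size)))
        res = fit_thermogram(tg, "double_dependent")
        for name in ("kd1", "kd2", "dh1", "dh2", "q_dil"):
            assert res.stderr[name] >= 0 or math.isnan(res.stderr[name])

    def test_estimator_get_set_params_round_trip(self):
        f = ThermogramFitter(scheme="single_site", exclude_first=True)
        g = ThermogramFitter().set_params(**f.get_params())
        assert g.get_params() == f.get_params()
        with pytest.raises(ValueError):
            f.set_params(bogus=1)

    def test_predict_reproduces_fitted_curve(self, bench_protocol, bench_params):
        tg = simulate_thermogram(bench_protocol, bench_params)
        fitter = ThermogramFitter().fit(tg)
        pred = fitter.predict(tg.protocol)
        np.testing.assert_allclose(pred, tg.normalized, rtol=1e-6)

    def test_bootstrap_stderr_smoke(self, bench_params):
        proto = TitrationProtocol.vp_itc_default(n_injections=20)
        rng = np.random.default_rng(5)
        heats = np.asarray(simulate_thermogram(proto, bench_params).heats)
        tg = Thermogram(proto, tuple(heats + rng.normal(0, 0.3, heats.size)))
        fitter = ThermogramFitter().fit(tg)
        se = fitter.bootstrap_stderr(tg, n_boot=3, seed=1)
        assert set(se) == {"kd1", "kd2", "dh1", "dh2", "q_dil"}
        assert se["kd1"] > 0


class TestCompareModels:
    def test_double_dependent_wins_on_biphasic_data(self, bench_protocol, bench_params):
        rng = np.random.default_rng(3)
        heats = np.asarray(simulate_thermogram(bench_protocol, bench_params).heats)
        tg = Thermogram(bench_protocol, tuple(heats + rng.normal(0, 0.5, heats.size)))
        best, worst = compare_models(tg)
        assert best.model_tag == "double_dependent"
        assert worst.aic - best.aic > 10

    def test_single_site_not_beaten_on_single_site_data(self, bench_protocol):
        truth = BindingParameters(kd1=2.9e-6, kd2=1e9, dh1=-8000.0, dh2=0.0)
        rng = np.random.default_rng(7)
        heats = np.asarray(simulate_thermogram(bench_protocol, truth).heats)
        tg = Thermogram(bench_protocol, tuple(heats + rng.normal(0, 0.5, heats.size)))
        results = {r.model_tag: r for r in compare_models(tg)}
        assert results["double_dependent"].aic - results["single_site"].aic > -2

    def test_zero_heats_converge_to_zero_enthalpy(self, bench_protocol):
        tg = Thermogram(bench_protocol, (0.0,) * bench_protocol.n_injections)
        for res in compare_models(tg):
            assert abs(res.params.dh1) < 1e-6
            assert res.rss < 1e-12
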