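import numpy as np
import pytest

from apcva import (
    BANDS,
    ObservableSeries,
    band_series,
    build_network,
    cofactor_activity,
    fit_monoexponential,
    initial_rate,
    normalize_rmv,
    preset,
    prothrombinase_activity,
    run_scenario,
    simulate,
)
from apcva.kinetics import state_vector
from apcva.network import SPECIES_INDEX


class TestBands:
    def test_initial_state_is_all_heavy_chain(self, default_network):
        tc = simulate(default_network, {"FVa": 20e-9}, 10.0, sample_times=[0, 10])
        assert band_series(tc, "HC").values[0] == pytest.approx(20e-9)
        for band in BANDS:
            if band != "HC":
                assert band_series(tc, band).values[0] == 0.0

    @pytest.mark.parametrize("fixture", ["fig3_current_result", "fig9_result"])
    def test_n_terminal_band_partition(self, fixture, request):
        """Every FVa molecule has exactly one N-terminal state, so
        HC + 1-506 + 1-306 equals the total cofactor pool at all times."""
        result = request.getfixturevalue(fixture)
        tc = result.timecourse
        total = (
            band_series(tc, "HC").values
            + band_series(tc, "1-506").values
            + band_series(tc, "1-306").values
        )
        np.testing.assert_allclose(total, result.config.fva_total, rtol=1e-6)

    def test_c_terminal_fragment_bookkeeping(self, fig3_current_result):
        """The 307-679/709 fragment appears only via Arg306 cleavage of the
        intact chain and is conserved once created: band total equals the
        1-306 band minus the doubly-cleaved contributions."""
        tc = fig3_current_result.timecourse
        b307 = band_series(tc, "307-679/709").values
        assert b307[0] == 0.0
        assert np.all(b307 >= -1e-18)
        # every 307-506 fragment coexists with a 507-679/709 fragment
        b37506 = band_series(tc, "307-506").values
        b507 = band_series(tc, "507-679/709").values
        assert np.all(b507 >= b37506 - 1e-18)

    def test_unknown_band_rejected(self, fig3_current_result):
        with pytest.raises(KeyError):
            band_series(fig3_current_result.timecourse, "1-999")


class TestActivities:
    def test_no_apc_means_constant_activity(self, default_network):
        tc = simulate(default_network, {"FVa": 20e-9}, 300.0)
        act = cofactor_activity(tc)
        np.testing.assert_allclose(act.values, 1.0, rtol=1e-10)

    def test_cofactor_activity_equals_relative_hc(self, fig3_current_result):
        tc = fig3_current_result.timecourse
        hc = band_series(tc, "HC")
        act = cofactor_activity(tc)
        np.testing.assert_allclose(act.values, hc.values / hc.values[0], rtol=1e-12)

    def test_half_activity_lost_within_a_minute(self, fig3_current_result):
        """0.5 nM APC on 20 nM FVa: ~50 % cofactor activity loss at 1 min."""
        act = fig3_current_result.observables["cofactor_activity"]
        assert act.value_at(60.0) == pytest.approx(0.50, abs=0.10)

    def test_partially_cleaved_cofactor_retains_one_fifth_activity(
        self, default_network
    ):
        y = state_vector(default_network, {"FVai506": 20e-9})
        tc = simulate(default_network, y, 1.0, sample_times=[0, 1])
        act = prothrombinase_activity(tc)
        assert act.values[0] == pytest.approx(0.2)

    def test_activity_bounds(self, fig9_result):
        act = prothrombinase_activity(fig9_result.timecourse)
        assert np.all(act.values <= 1.0 + 1e-12)
        assert np.all(act.values >= 0.0)

    def test_prothrombinase_at_least_fifth_of_cofactor_pool_before_shedding(
        self, default_network
    ):
        """Before any fragment dissociation, every cofactor is intact or
        partially cleaved, so activity ≥ 0.2 × (cofactor-capable pool)."""
        tc = simulate(default_network, {"FVa": 20e-9, "APC": 2e-9}, 20.0)
        act = prothrombinase_activity(tc).values
        capable = (
            band_series(tc, "HC").values + band_series(tc, "1-506").values
        ) / 20e-9
        assert np.all(act >= 0.2 * capable - 1e-9)


class TestNormalization:
    def test_monotone_decay_normalizes_to_one_at_zero(self, fig3_current_result):
        hc = normalize_rmv(fig3_current_result.observables["HC"])
        assert hc.values[0] == pytest.approx(1.0)
        assert np.max(hc.values) == pytest.approx(1.0)

    def test_peaked_trace_keeps_argmax(self, fig3_hockin_result):
        band = fig3_hockin_result.observables["1-506"]
        assert normalize_rmv(band).peak_time() == band.peak_time()

    def test_adjusted_arg306_rate_clears_fragment_faster(
        self, fig3_current_result, fig3_hockin_result
    ):
        """The human-adjusted (3x faster) Arg306 rate moves the 1-506 peak
        earlier and clears it harder by 20 min than the bovine-derived rate."""
        cur = fig3_current_result.observables["1-506"]
        hok = fig3_hockin_result.observables["1-506"]
        assert cur.peak_time() < hok.peak_time()
        cur_frac = cur.value_at(1200) / max(cur.values)
        hok_frac = hok.value_at(1200) / max(hok.values)
        assert cur_frac < hok_frac

    def test_all_zero_series_rejected(self):
        s = ObservableSeries("x", np.array([0.0, 1.0]), np.zeros(2))
        with pytest.raises(ValueError):
            normalize_rmv(s)


class TestInitialRate:
    def test_exact_exponential_recovers_rate(self):
        """A pure exp(-0.01 t) decay from 20 nM has an initial slope of
        0.01 x 20 nM = 200 pM/s."""
        t = np.array([0.0, 30, 60, 120, 180, 240, 360])
        s = ObservableSeries("HC", t, np.exp(-0.01 * t), normalized=True)
        assert initial_rate(s, 20e-9) == pytest.approx(200.0, rel=1e-6)

    def test_noisy_exponential_recovered_within_ten_percent(self, rng):
        t = np.linspace(0, 360, 361)
        clean = np.exp(-0.008 * t)
        noisy = clean * (1 + 0.05 * rng.standard_normal(len(t)))
        noisy = np.clip(noisy, 1e-9, None)
        s = ObservableSeries("HC", t, noisy, normalized=True)
        rate = initial_rate(s, 20e-9, sample_times=t[::10])
        assert rate == pytest.approx(0.008 * 20e-9 * 1e12, rel=0.10)

    def test_plateau_added_only_when_it_earns_its_keep(self):
        t = np.array([0.0, 30, 60, 120, 180, 240, 360])
        with_floor = 0.6 * np.exp(-0.02 * t) + 0.4
        fit = fit_monoexponential(
            ObservableSeries("x", t, with_floor, normalized=True)
        )
        assert fit.used_plateau
        assert fit.plateau == pytest.approx(0.4, abs=0.05)
        pure = np.exp(-0.02 * t)
        fit2 = fit_monoexponential(ObservableSeries("x", t, pure, normalized=True))
        assert fit2.rate == pytest.approx(0.02, rel=1e-4)

    def test_too_few_points_rejected(self):
        s = ObservableSeries("x", np.array([0.0, 30.0]), np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            initial_rate(s, 20e-9)

    def test_saturating_fxa_scenario_initial_rate(self):
        """2 nM APC on prothrombinase preformed at K_D 0.5 nM: the simulated
        initial heavy-chain proteolysis rate lands near the printed 86 pM/s."""
        res = run_scenario(preset("fig4c_sat"))
        rate = initial_rate(res.observables["HC"], 20e-9)
        assert rate == pytest.approx(86.0, rel=0.15)
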