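"""Fitting layer: round trips, model-order selection, splice, two-window analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petkin as pk
from petkin.exceptions import InputError
from petkin.fitting import runs_test_pvalue
from petkin.presets import long_pair_acquisitions, preset_library, turnover_acquisition
from petkin.simulate import AcquisitionSpec, Trace


def make_trace(model, t):
    return Trace(np.asarray(t, dtype=float), model(np.asarray(t, dtype=float)))


class TestMultiExpRoundTrips:
    def test_one_phase_noiseless_machine_precision(self):
        m = pk.MultiExpModel(10.0, (pk.Phase(-5.0, 40.0),))
        fit = pk.fit_multiexp(make_trace(m, np.linspace(0, 0.25, 2000)), 1)
        assert fit.model.baseline == pytest.approx(10.0, rel=1e-6)
        assert fit.model.phases[0].amplitude == pytest.approx(-5.0, rel=1e-6)
        assert fit.model.phases[0].rate == pytest.approx(40.0, rel=1e-6)

    def test_three_phase_noiseless(self):
        m = pk.MultiExpModel(
            10.0,
            (pk.Phase(-2.5, 800.0), pk.Phase(-1.5, 60.0), pk.Phase(-1.0, 4.0)),
        )
        fit = pk.fit_multiexp(make_trace(m, np.linspace(0, 1.25, 6000)), 3)
        for p, (k, c) in zip(fit.model.phases, [(800, 0.5), (60, 0.3), (4, 0.2)]):
            assert p.rate == pytest.approx(k, rel=0.01)
        for got, want in zip(fit.contributions, (0.5, 0.3, 0.2)):
            assert got == pytest.approx(want, abs=0.01)

    def test_stretched_round_trip(self):
        m = pk.MultiExpModel(5.0, (pk.Phase(2.0, 3.0, 0.7),))
        fit = pk.fit_multiexp(
            make_trace(m, np.linspace(0, 5, 3000)), 1, allow_stretched=[True]
        )
        assert fit.model.phases[0].beta == pytest.approx(0.7, rel=1e-3)
        assert fit.model.phases[0].rate == pytest.approx(3.0, rel=1e-3)

    def test_determinism(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 1500)
        m = pk.MultiExpModel(8.0, (pk.Phase(-3.0, 50.0), pk.Phase(1.0, 2.0)))
        tr = Trace(t, m(t) + rng.normal(0, 0.03, t.size))
        f1 = pk.fit_multiexp(tr, 2)
        f2 = pk.fit_multiexp(tr, 2)
        assert f1.rates == f2.rates
        assert f1.sse == f2.sse

    def test_contributions_sum_to_one(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 1, 1200)
        m = pk.MultiExpModel(8.0, (pk.Phase(-3.0, 50.0), pk.Phase(1.0, 2.0)))
        tr = Trace(t, m(t) + rng.normal(0, 0.03, t.size))
        fit = pk.fit_multiexp(tr, 2)
        assert sum(fit.contributions) == pytest.approx(1.0, abs=1e-9)

    def test_nested_sse_monotone(self):
        # dropping the smallest-contribution phase can never improve the fit
        rng = np.random.default_rng(2)
        t = np.linspace(0, 1, 2000)
        m = pk.MultiExpModel(8.0, (pk.Phase(-3.0, 60.0), pk.Phase(-0.5, 5.0)))
        tr = Trace(t, m(t) + rng.normal(0, 0.03, t.size))
        assert pk.fit_multiexp(tr, 1).sse >= pk.fit_multiexp(tr, 2).sse

    def test_too_few_samples_rejected(self):
        m = pk.MultiExpModel(1.0, (pk.Phase(1.0, 1.0),))
        with pytest.raises(InputError):
            pk.fit_multiexp(make_trace(m, np.linspace(0, 1, 20)), 3)

    def test_rate_uncertain_flag(self):
        m = pk.MultiExpModel(10.0, (pk.Phase(-5.0, 2500.0),))
        fit = pk.fit_multiexp(make_trace(m, np.linspace(1e-4, 0.01, 800)), 1)
        assert fit.rate_uncertain == (True,)

    @given(
        n_phases=st.integers(1, 2),
        k0=st.floats(2.0, 50.0),
        sep=st.floats(5.0, 30.0),
        a0=st.sampled_from([-3.0, -1.0, 1.5]),
        a1=st.sampled_from([-2.0, 1.0]),
    )
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_round_trip_identifiability(self, n_phases, k0, sep, a0, a1):
        # noiseless traces with >= 5x separated rates refit to within 1%
        phases = [pk.Phase(a0, k0 * sep)]
        if n_phases == 2:
            phases.append(pk.Phase(a1, k0))
        m = pk.MultiExpModel(10.0, tuple(phases))
        t = np.linspace(0, 5.0 / k0, 4000)
        fit = pk.fit_multiexp(Trace(t, m(t)), n_phases)
        for got, want in zip(fit.model.phases, m.phases):
            assert got.rate == pytest.approx(want.rate, rel=0.01)
            assert got.amplitude == pytest.approx(want.amplitude, rel=0.01)


class TestModelOrderSelection:
    def test_single_exponential_chooses_one_phase(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 0.5, 3000)
        m = pk.MultiExpModel(10.0, (pk.Phase(-4.0, 30.0),))
        tr = Trace(t, m(t) + rng.normal(0, 0.03, t.size))
        assert pk.select_model_order(tr).n_phases == 1

    def test_chosen_rates_identifiably_separated(self, qm):
        rec = preset_library("wt_ATP")
        from petkin.presets import binding_acquisition

        for seed in range(3):
            tr = pk.generate_binding_trace(
                rec.scheme, "lid", binding_acquisition(rec, seed), qm
            )
            fit = pk.select_model_order(tr)
            rates = np.sort(fit.rates)
            assert np.all(rates[1:] / rates[:-1] >= 1.5)


class TestSingleTurnoverFit:
    def test_noiseless_round_trip(self):
        m = pk.SingleTurnoverModel(2.0, 10.0, 0.01, 1e-4, 0.0)
        acq = AcquisitionSpec(duration=40000.0, n_samples=900, dead_time=0.0,
                              noise_sigma=0.0, rng_seed=0)
        tr = pk.generate_single_turnover_trace(m, acq)
        fit = pk.fit_single_turnover(tr)
        assert fit.F0 == pytest.approx(2.0, rel=1e-3)
        assert fit.Fmax == pytest.approx(10.0, rel=1e-3)
        assert fit.k1 == pytest.approx(0.01, rel=1e-3)
        assert fit.k2 == pytest.approx(1e-4, rel=1e-3)

    def test_confidence_flags(self):
        m = pk.SingleTurnoverModel(2.0, 10.0, 0.01, 1e-4, 0.0)
        acq = AcquisitionSpec(duration=40000.0, n_samples=900, dead_time=0.0, rng_seed=1)
        fit = pk.fit_single_turnover(pk.generate_single_turnover_trace(m, acq))
        assert fit.high_confidence["Fmax"] and fit.high_confidence["k2"]
        assert not (fit.high_confidence["F0"] or fit.high_confidence["k1"])

    def test_null_control_flagged_non_informative(self):
        rec = preset_library("turnover_ADP_null")
        tr = pk.generate_single_turnover_trace(rec.turnover_model, turnover_acquisition(rec, 0))
        fit = pk.fit_single_turnover(tr)
        assert "non_informative" in fit.flags

    def test_peptide_stimulated_recovery_over_seeds(self):
        rec = preset_library("turnover_ATP_pep65")
        k2s = []
        for seed in range(10):
            tr = pk.generate_single_turnover_trace(
                rec.turnover_model, turnover_acquisition(rec, seed)
            )
            k2s.append(pk.fit_single_turnover(tr).k2)
        assert np.mean(k2s) == pytest.approx(rec.turnover_model.k2, rel=0.05)


class TestSpliceAndTwoWindows:
    def test_splice_arithmetic(self):
        short = Trace(np.linspace(0, 0.25, 101), np.full(101, 9.0))
        long = Trace(np.linspace(0.01, 250, 400), np.full(400, 4.0))
        short_fit = pk.fit_multiexp(
            Trace(np.linspace(0, 0.25, 101), 9.8 - 0.8 * (1 - np.exp(-50 * np.linspace(0, 0.25, 101)))), 1
        )
        spliced = pk.splice_long_trace(short_fit, short, long, target_start=10.0)
        c = (10.0 - short_fit.model.baseline) + (9.0 - 4.0)
        assert spliced.metadata["splice_constant_au"] == pytest.approx(c)
        assert spliced.value_at(0.025) == pytest.approx(4.0 + c)

    def test_splice_identity_when_aligned(self):
        # both grids contain the 0.025 s reference point exactly
        t = np.linspace(0, 0.25, 201)
        y = 10.0 - 1.0 * (1 - np.exp(-80 * t))
        short = Trace(t, y)
        fit = pk.fit_multiexp(short, 1)
        tl = np.concatenate([[0.005, 0.025], np.linspace(1.0, 250.0, 300)])
        long = Trace(tl, 10.0 - 1.0 * (1 - np.exp(-80 * tl)))
        spliced = pk.splice_long_trace(fit, short, long)
        assert spliced.metadata["splice_constant_au"] == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(spliced.fluorescence, long.fluorescence, atol=1e-6)

    def test_splice_cancels_injected_offset(self, qm):
        rec = preset_library("R151A")
        for seed in (0, 1, 2):
            acq_s, acq_l = long_pair_acquisitions(seed)
            short, long = pk.generate_long_trace_pair(
                rec.long_scheme, "sbdb_ib", acq_s, acq_l, qm
            )
            summary = pk.analyze_two_windows(short, long, "biexp")
            offset = long.metadata["voltage_offset_au"]
            c = summary.spliced_long.metadata["splice_constant_au"]
            y0 = summary.fast_fit.model.baseline
            # the splice constant undoes the injected offset and re-anchors
            # the combined kinetics to start at 10 AU
            assert abs((c + offset) - (10.0 - y0)) < 3 * acq_l.noise_sigma

    def test_reference_point_outside_span_rejected(self):
        t = np.linspace(0.05, 0.25, 100)
        tr = Trace(t, np.ones(100))
        fit = pk.fit_multiexp(Trace(np.linspace(0, 0.25, 100), np.ones(100) + np.exp(-np.linspace(0, 0.25, 100))), 1)
        with pytest.raises(InputError):
            pk.splice_long_trace(fit, tr, tr)

    def test_overlapping_windows_rejected(self, qm):
        rec = preset_library("R151A")
        acq_s, acq_l = long_pair_acquisitions(0)
        short, long = pk.generate_long_trace_pair(rec.long_scheme, "sbdb_ib", acq_s, acq_l, qm)
        with pytest.raises(InputError):
            pk.analyze_two_windows(short, long, "biexp", fast_window=(0.0023, 20.0))

    def test_noiseless_slow_rate_recovered_from_late_window(self, qm):
        # a user-built scheme with a single 0.02 1/s detachment step: the
        # late-window fit recovers the slow rate within 1% on noiseless data
        sch = pk.KineticScheme(
            ("apo", "docked", "s_state"), {"p": (20.0, 14.0, 37.0)}, (200.0, 0.02),
            (pk.Subpopulation(1.0, 200.0),),
        )
        acq_s = AcquisitionSpec(duration=0.25, n_samples=2000, noise_sigma=0.0, rng_seed=0)
        acq_l = AcquisitionSpec(duration=250.0, n_samples=1500, spacing="log",
                                noise_sigma=0.0, rng_seed=1)
        _, long = pk.generate_long_trace_pair(sch, "p", acq_s, acq_l, qm, offset_range=0.0)
        fit = pk.fit_multiexp(long.window(10.0, 250.0), 1)
        assert fit.model.phases[0].rate == pytest.approx(0.02, rel=0.01)

    def test_wt_pair_has_no_slow_amplitude(self, qm):
        rec = preset_library("wt_ATP")
        acq_s, acq_l = long_pair_acquisitions(4)
        short, long = pk.generate_long_trace_pair(rec.long_scheme, "sbdb_ib", acq_s, acq_l, qm)
        summary = pk.analyze_two_windows(short, long, "biexp")
        assert summary.amplitude_ratio < 0.05
        assert summary.amplitude_ratio >= 0.0

    def test_unknown_family_rejected(self, qm):
        rec = preset_library("R151A")
        acq_s, acq_l = long_pair_acquisitions(0)
        short, long = pk.generate_long_trace_pair(rec.long_scheme, "sbdb_ib", acq_s, acq_l, qm)
        with pytest.raises(InputError):
            pk.analyze_two_windows(short, long, "quadexp")


class TestRunsTest:
    def test_structured_residuals_detected(self):
        r = np.concatenate([np.ones(50), -np.ones(50)])
        assert runs_test_pvalue(r) < 1e-6

    def test_random_residuals_pass(self):
        rng = np.random.default_rng(0)
        assert runs_test_pvalue(rng.normal(size=500)) > 0.05
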