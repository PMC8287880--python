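"""Tests for the synthetic mother-machine data generator."""

import numpy as np
import pytest

from sigvsim import (
    CircuitParameters,
    GeneratorConfig,
    compare_activation_by_prestress,
    filter_overshooting,
    generate_mother_machine_ensemble,
    generate_parametric_traces,
    generate_priming_lineages,
    generate_reporter_trace,
    instantaneous_growth_rate,
    step_protocol,
    summarize_activation,
    survival_fraction,
)
from sigvsim.protocols import constant_protocol
from sigvsim.ssa import Trajectory
from sigvsim.synthetic import _reporter_filter
from sigvsim.params import VariantSpec


def const_sigv_trajectory(level, duration=1000.0, dt=10.0):
    times = np.arange(0.0, duration + 1e-9, dt)
    states = np.zeros((len(times), 3), dtype=np.int64)
    states[:, 0] = level
    return Trajectory(times=times, states=states, seed=0,
                      variant=VariantSpec(), protocol=constant_protocol(0.0, duration))


class TestReporterTrace:
    def test_zero_sigma_gives_flat_leak_plateau(self, params):
        # leak production v0 filtered through maturation and dilution:
        # steady state = v0/k_deg * (mature fraction)
        cfg = GeneratorConfig(measurement_noise=0.0)
        tr = generate_reporter_trace(const_sigv_trajectory(0), cfg)
        km, kd = 1 / cfg.maturation_time, params.k_deg
        expected = params.v0 / (km + kd) * km / kd
        assert np.allclose(tr.fluorescence, expected, rtol=1e-9)

    def test_maturation_zero_has_shorter_lag_than_fifteen(self):
        # a step in sigma-V: the reporter half-rise lags more with longer
        # maturation, and the zero-maturation trace leads pointwise
        times = np.arange(0.0, 3000.0, 10.0)
        states = np.zeros((len(times), 3), dtype=np.int64)
        states[times >= 500, 0] = 500
        tr = Trajectory(times=times, states=states, seed=0,
                        variant=VariantSpec(),
                        protocol=constant_protocol(0.0, 3000.0))
        lags = {}
        for mat in (0.0, 15.0, 60.0):
            cfg = GeneratorConfig(maturation_time=mat, measurement_noise=0.0)
            rep = generate_reporter_trace(tr, cfg).fluorescence
            half = (rep[0] + rep[-1]) / 2
            lags[mat] = times[np.nonzero(rep >= half)[0][0]] - 500.0
        assert lags[0.0] < lags[15.0] < lags[60.0]

    def test_first_order_filter_matches_analytic_step_response(self, params):
        # step input u0 -> u1 through the immature/mature cascade has the
        # closed-form two-exponential solution
        dt, mat, kd = 1.0, 15.0, params.k_deg
        u = np.full(600, 2.0)
        u[:100] = 0.5
        out = _reporter_filter(u, dt, mat, kd)
        km = 1 / mat
        a_i, a_m = km + kd, kd
        t = np.arange(500) * dt
        m0, m1 = km * 0.5 / (a_i * a_m), km * 2.0 / (a_i * a_m)
        # M(t) relaxing from m0 to m1 with both rates
        expected = m1 + (m0 - m1) * (a_i * np.exp(-a_m * t) - a_m * np.exp(-a_i * t)) / (a_i - a_m)
        assert np.allclose(out[100:], expected, rtol=1e-6)

    def test_deterministic_for_fixed_seed(self):
        cfg = GeneratorConfig(measurement_noise=0.2)
        tr = const_sigv_trajectory(50)
        a = generate_reporter_trace(tr, cfg, seed=4)
        b = generate_reporter_trace(tr, cfg, seed=4)
        assert np.array_equal(a.fluorescence, b.fluorescence)


@pytest.fixture(scope="module")
def dataset():
    cfg = GeneratorConfig()
    prot = step_protocol(200, 1.0, 1400)
    return generate_mother_machine_ensemble(cfg, 60, prot, seed=11), cfg


class TestMotherMachineEnsemble:
    def test_reproducible_from_seed(self):
        cfg = GeneratorConfig()
        prot = step_protocol(200, 1.0, 800)
        t1, g1 = generate_mother_machine_ensemble(cfg, 5, prot, seed=3)
        t2, g2 = generate_mother_machine_ensemble(cfg, 5, prot, seed=3)
        assert all(np.array_equal(a.fluorescence, b.fluorescence)
                   for a, b in zip(t1, t2))
        assert g1.equals(g2)

    def test_activation_times_recovered_within_one_frame(self, dataset):
        (traces, truth), cfg = dataset
        summaries = summarize_activation(traces, final_window=300)
        rec = np.array([s.activation_time if not s.censored else np.nan
                        for s in summaries])
        tru = truth["switch_time_reporter"].to_numpy()
        ok = np.abs(rec - tru) <= cfg.frame_interval
        valid = ~np.isnan(rec) & ~np.isnan(tru)
        assert valid.sum() >= 50
        assert ok[valid].mean() >= 0.95

    def test_sick_labels_recovered_by_width_filter(self, dataset):
        (traces, truth), _ = dataset
        kept, removed = filter_overshooting(traces)
        assert {tr.cell_id for tr in removed} == \
            set(truth.loc[truth.sick, "cell_id"])

    def test_growth_rates_exact_in_noiseless_lengths(self, dataset):
        (traces, truth), _ = dataset
        for tr in traces[:10]:
            rates = instantaneous_growth_rate(tr)
            assert np.allclose(rates.growth_rate,
                               truth.growth_rate[tr.cell_id], rtol=1e-9)

    def test_zero_noise_zero_maturation_recovery_is_exact(self):
        cfg = GeneratorConfig(measurement_noise=0.0, maturation_time=0.0,
                              sick_fraction=0.0)
        prot = step_protocol(200, 2.0, 1400)
        traces, truth = generate_mother_machine_ensemble(cfg, 20, prot, seed=5)
        summaries = summarize_activation(traces, final_window=300)
        for s in summaries:
            tru = truth.loc[truth.cell_id == s.cell_id,
                            "switch_time_reporter"].iloc[0]
            if s.censored or np.isnan(tru):
                continue
            assert s.activation_time == pytest.approx(tru, abs=1e-9)

    def test_sick_fraction_within_binomial_interval(self):
        cfg = GeneratorConfig(sick_fraction=0.2)
        prot = step_protocol(100, 1.0, 400)
        _, truth = generate_mother_machine_ensemble(cfg, 200, prot, seed=21)
        k = truth.sick.sum()
        # 99% binomial interval around 0.2 at n=200
        assert 20 <= k <= 60


class TestParametricTraces:
    def test_programmed_prestress_correlation_detected(self):
        cfg = GeneratorConfig(prestress_correlation=0.8, measurement_noise=0.03)
        traces, truth = generate_parametric_traces(cfg, 100, seed=13)
        summaries = summarize_activation(traces, final_window=100)
        res = compare_activation_by_prestress(traces, summaries)
        assert res.computable
        assert res.reject_null
        assert res.mean_time_high < res.mean_time_low

    def test_zero_correlation_times_similar(self):
        cfg = GeneratorConfig(prestress_correlation=0.0, measurement_noise=0.03)
        traces, truth = generate_parametric_traces(cfg, 150, seed=14)
        summaries = summarize_activation(traces, final_window=100)
        res = compare_activation_by_prestress(traces, summaries)
        # no programmed association: group means within one frame-ish
        assert abs(res.mean_time_high - res.mean_time_low) < 60


class TestPrimingLineages:
    def test_degenerate_survival_rules(self):
        prot = step_protocol(100, 1.0, 700)
        for p_surv, expected in [(0.0, 0.0), (1.0, 1.0)]:
            cfg = GeneratorConfig(survival_rule=lambda x, p=p_surv: p)
            forest, truth = generate_priming_lineages(cfg, 6, prot,
                                                      lethal_time=500, seed=2)
            for method in ("top3_longest", "channel_end_exclusion"):
                frac, _ = survival_fraction(forest, method)
                assert frac == expected

    def test_programmed_fraction_recovered_by_both_methods(self):
        cfg = GeneratorConfig(survival_rule=lambda x: 0.4)
        prot = step_protocol(100, 1.0, 700)
        forest, truth = generate_priming_lineages(cfg, 40, prot,
                                                  lethal_time=500, seed=8)
        for method in ("top3_longest", "channel_end_exclusion"):
            frac, _ = survival_fraction(forest, method)
            # binomial 99.7% interval at >= 120 scored cells
            assert abs(frac - 0.4) < 3 * np.sqrt(0.4 * 0.6 / 120)

    def test_step_rule_survivors_have_higher_reporter(self):
        prot = step_protocol(100, 1.0, 700)
        cfg = GeneratorConfig(survival_rule=lambda x: 0.95 if x > 80 else 0.05)
        forest, truth = generate_priming_lineages(cfg, 25, prot,
                                                  lethal_time=500, seed=4)
        surv = truth[truth.survived].reporter_at_lethal
        dead = truth[~truth.survived].reporter_at_lethal
        assert surv.mean() > dead.mean()

    def test_lethal_after_movie_end_rejected(self):
        cfg = GeneratorConfig()
        with pytest.raises(ValueError):
            generate_priming_lineages(cfg, 2, step_protocol(10, 1.0, 100),
                                      lethal_time=200, seed=1)
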