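"""Peak metrics against closed forms and a dense-grid EMG oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize, stats

from amrtkit.chromatography import (
    SuitabilityCriteria,
    Trace,
    detect_main_peak,
    extract_trace,
    rank_conditions,
    screen_condition,
)
from amrtkit.simulate import (
    LCRunParams,
    PeakShapeParams,
    SimulatedLCRun,
    simulate_trace,
)

from conftest import make_compound

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


def emg_oracle(sigma: float, tau: float, grid_ms: float = 1.0):
    """Independent EMG metrics: root-finding on the analytic profile
    sampled at a 1 ms grid around the exact (dense-argmax) apex."""
    t = np.arange(-8 * sigma - 2 * tau, 8 * sigma + 10 * tau, grid_ms / 1000.0)
    if tau <= 0:
        y = np.exp(-(t**2) / (2 * sigma**2))
    else:
        y = stats.exponnorm.pdf(t, K=tau / sigma, loc=0.0, scale=sigma)
    apex_idx = int(np.argmax(y))
    apex_t, apex_y = t[apex_idx], y[apex_idx]
    half = apex_y / 2.0

    def f(x):
        if tau <= 0:
            return np.exp(-(x**2) / (2 * sigma**2)) - half
        return stats.exponnorm.pdf(x, K=tau / sigma, loc=0.0, scale=sigma) - half

    left = optimize.brentq(f, t[0], apex_t)
    right = optimize.brentq(f, apex_t, t[-1])
    a, b = apex_t - left, right - apex_t
    return {
        "width50": right - left,
        "symmetry50": 100.0 * min(a, b) / max(a, b),
    }


class TestDetectMainPeak:
    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
    def test_gaussian_width_matches_closed_form(self, sigma):
        trace = simulate_trace(PeakShapeParams(sigma=sigma, tau=0.0, sampling_hz=20))
        peak = detect_main_peak(trace)
        assert peak is not None
        assert peak.width50 == pytest.approx(FWHM_FACTOR * sigma, rel=0.01)

    @pytest.mark.parametrize("sigma,hz", [(0.5, 25), (1.0, 12), (2.0, 10)])
    def test_symmetric_peak_symmetry_is_100(self, sigma, hz):
        trace = simulate_trace(PeakShapeParams(sigma=sigma, tau=0.0, sampling_hz=hz))
        peak = detect_main_peak(trace)
        assert peak.symmetry50 == pytest.approx(100.0, abs=0.5)

    def test_emg_symmetry_matches_dense_oracle(self):
        sigma, tau = 0.8, 1.5
        trace = simulate_trace(PeakShapeParams(sigma=sigma, tau=tau, sampling_hz=20))
        peak = detect_main_peak(trace)
        oracle = emg_oracle(sigma, tau)
        assert peak.symmetry50 < 100.0
        assert peak.symmetry50 == pytest.approx(oracle["symmetry50"], rel=0.02)
        assert peak.width50 == pytest.approx(oracle["width50"], rel=0.02)

    def test_symmetry_strictly_decreasing_in_tail_ratio(self):
        sigma = 1.0
        ratios = [0.1, 0.5, 1.0, 2.0, 5.0]
        oracle_values = [emg_oracle(sigma, r * sigma)["symmetry50"] for r in ratios]
        measured = []
        for r in ratios:
            trace = simulate_trace(PeakShapeParams(sigma=sigma, tau=r * sigma, sampling_hz=20))
            measured.append(detect_main_peak(trace).symmetry50)
        assert all(a > b for a, b in zip(oracle_values, oracle_values[1:]))
        assert all(a > b for a, b in zip(measured, measured[1:]))
        for m, o in zip(measured, oracle_values):
            assert m == pytest.approx(o, rel=0.03)

    def test_flat_top_flags_overload(self):
        t = np.arange(0, 60, 0.1)
        y = np.minimum(1e6 * np.exp(-((t - 30) ** 2) / (2 * 1.5**2)), 8e5)
        peak = detect_main_peak(Trace(t, y))
        assert peak is not None and peak.overloaded

    def test_narrow_peak_not_overloaded(self):
        trace = simulate_trace(PeakShapeParams(sigma=1.0, tau=0.0, sampling_hz=20))
        assert not detect_main_peak(trace).overloaded

    def test_all_zero_and_monotone_traces_yield_no_peak(self):
        t = np.arange(0, 10, 0.5)
        assert detect_main_peak(Trace(t, np.zeros_like(t))) is None
        assert detect_main_peak(Trace(t, np.linspace(0, 100, t.size))) is None

    def test_intensity_scaling_changes_no_metric(self):
        trace = simulate_trace(PeakShapeParams(sigma=1.0, tau=1.0, sampling_hz=15))
        peak = detect_main_peak(trace)
        scaled = detect_main_peak(Trace(trace.times, trace.intensities * 977.3))
        assert scaled.width50 == pytest.approx(peak.width50)
        assert scaled.symmetry50 == pytest.approx(peak.symmetry50)
        assert scaled.tailing_factor == pytest.approx(peak.tailing_factor)
        assert scaled.overloaded == peak.overloaded


class TestExtractTrace:
    def test_planted_compound_yields_peak_at_planted_rt(self):
        compounds = [make_compound(1, 200.0)]
        run = SimulatedLCRun(compounds, "positive", LCRunParams(seed=4))
        mz = 200.0 + 1.007276
        trace = extract_trace(run, mz, 5.0)
        peak = detect_main_peak(trace)
        planted_rt_s = run.peaks["T001"].rt * 60.0
        assert peak is not None
        assert abs(peak.apex_time - planted_rt_s) < 1.0

    def test_unmatched_mz_gives_all_zero_trace(self):
        run = SimulatedLCRun([make_compound(1, 200.0)], "positive", LCRunParams(seed=4))
        trace = extract_trace(run, 555.5, 5.0)
        assert np.all(trace.intensities == 0.0)

    def test_close_masses_do_not_cross_contaminate(self):
        # 100 ppm apart at 5 ppm tolerance: each trace sees only its own compound
        m1, m2 = 400.0, 400.0 * (1 + 100e-6)
        compounds = [make_compound(1, m1), make_compound(2, m2)]
        run = SimulatedLCRun(compounds, "positive", LCRunParams(seed=9))
        mz1 = m1 + 1.007276
        mz2 = m2 + 1.007276
        t1 = extract_trace(run, mz1, 5.0)
        t2 = extract_trace(run, mz2, 5.0)
        p1, p2 = detect_main_peak(t1), detect_main_peak(t2)
        assert abs(p1.apex_time - run.peaks["T001"].rt * 60) < 1.0
        assert abs(p2.apex_time - run.peaks["T002"].rt * 60) < 1.0


class TestScreenCondition:
    def test_planted_pass_counts_recovered(self):
        # one run, 20 compounds: 12 planted well-behaved, 8 with strong tails
        from amrtkit.simulate import emg_profile

        good = [make_compound(i, 150.0 + 20 * i) for i in range(12)]
        bad = [make_compound(100 + i, 600.0 + 20 * i) for i in range(8)]
        rng = np.random.default_rng(2)
        times = np.arange(0.0, 900.0, 1 / 6.0)

        class PlantedRun:
            polarity = "positive"

            def __init__(self):
                self.profiles = {}
                for k, compound in enumerate(good + bad):
                    sigma = float(rng.uniform(1.0, 1.3))
                    tau = 0.02 * sigma if k < 12 else 3.0 * sigma
                    rt_s = float(rng.uniform(60.0, 840.0))
                    mz = compound.neutral_mass + 1.007276
                    self.profiles[mz] = 1e6 * emg_profile(times, rt_s, sigma, tau)

            def ms1_scans(self):
                mz_arr = np.array(list(self.profiles))
                mat = np.vstack(list(self.profiles.values()))
                out = []
                for i, t in enumerate(times):
                    keep = mat[:, i] > 1.0
                    out.append((float(t), mz_arr[keep], mat[keep, i]))
                return out

        result = screen_condition(PlantedRun(), good + bad, SuitabilityCriteria())
        assert result.n_both == 12
        assert result.n_found == 20

    def test_vacuous_criteria_pass_everything_found(self):
        compounds = [make_compound(i, 150.0 + 25 * i) for i in range(10)]
        run = SimulatedLCRun(compounds, "positive", LCRunParams(seed=5))
        criteria = SuitabilityCriteria(symmetry_min=0.0, width_bounds=(1e-6, 1e6))
        result = screen_condition(run, compounds, criteria)
        assert result.n_both == result.n_found

    def test_symmetry_exactly_at_threshold_fails_width_bounds_inclusive(self):
        from amrtkit.chromatography import ChromPeak

        crit = SuitabilityCriteria(symmetry_min=90.0, width_bounds=(1.8, 3.6))

        def peak(symmetry, width):
            return ChromPeak(
                apex_time=10.0, apex_intensity=1e6,
                left50_time=10.0 - width / 2, right50_time=10.0 + width / 2,
                width50=width, symmetry50=symmetry,
                tailing_factor=1.0, overloaded=False,
            )

        # symmetry threshold is strict ("above 90%"): exactly 90 fails
        assert crit.passes(peak(90.0, 2.5)) == (False, True)
        assert crit.passes(peak(90.01, 2.5)) == (True, True)
        # width bounds are inclusive ("between 1.8 and 3.6 s")
        assert crit.passes(peak(95.0, 1.8)) == (True, True)
        assert crit.passes(peak(95.0, 3.6)) == (True, True)
        assert crit.passes(peak(95.0, 3.61)) == (True, False)

    def test_totals_inequality_chain(self):
        compounds = [make_compound(i, 120.0 + 30 * i) for i in range(15)]
        run = SimulatedLCRun(
            compounds, "positive",
            LCRunParams(tau_over_sigma=0.6, found_fraction=0.8, seed=7),
        )
        res = screen_condition(run, compounds, SuitabilityCriteria())
        assert res.n_both <= min(res.n_symmetry, res.n_width)
        assert max(res.n_symmetry, res.n_width) <= res.n_found <= len(compounds)


class _FakeScreen:
    def __init__(self, n_both):
        self.n_both = n_both


class TestRankConditions:
    def test_better_in_both_polarities_ranks_first(self):
        results = [
            ("C18-ACN", {"positive": _FakeScreen(50), "negative": _FakeScreen(67)}),
            ("C18-MeOH", {"positive": _FakeScreen(29), "negative": _FakeScreen(40)}),
        ]
        ranking = rank_conditions(results)
        assert [r[0] for r in ranking] == ["C18-ACN", "C18-MeOH"]

    def test_min_rule_prefers_balanced_condition(self):
        # one polarity collapsing (6) loses to balanced (25, 25)
        results = [
            ("amide-A", {"positive": _FakeScreen(22), "negative": _FakeScreen(6)}),
            ("amide-B", {"positive": _FakeScreen(25), "negative": _FakeScreen(25)}),
        ]
        ranking = rank_conditions(results)
        assert ranking[0][0] == "amide-B"

    def test_single_condition(self):
        ranking = rank_conditions([("only", {"positive": _FakeScreen(10)})])
        assert ranking == [("only", 10, 10)]

    def test_tie_breaks_on_sum_then_label(self):
        results = [
            ("b", {"positive": _FakeScreen(10), "negative": _FakeScreen(12)}),
            ("a", {"positive": _FakeScreen(10), "negative": _FakeScreen(12)}),
            ("c", {"positive": _FakeScreen(10), "negative": _FakeScreen(20)}),
        ]
        ranking = rank_conditions(results)
        assert [r[0] for r in ranking] == ["c", "a", "b"]
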