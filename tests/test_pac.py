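"""Cycle segmentation, cycle filters, equalization, modulation index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ieegpac import (amplitude_floor_filter, equalize_phase_histogram,
                     modulation_index, rayleigh_test, reject_outlier_cycles,
                     segment_cycles, wrap_degrees)

FS = 512.0


def _phase_series(f_lf, duration, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return wrap_degrees(360.0 * f_lf * t)


class TestSegmentCycles:
    @pytest.mark.parametrize("f_lf,expected", [(1.0, 300), (0.75, 225)])
    def test_five_minute_block_cycle_count(self, f_lf, expected):
        table = segment_cycles(FS, phase=_phase_series(f_lf, 300.0))
        assert len(table) == expected

    @pytest.mark.parametrize("rate,expected", [(1.0, 300), (0.75, 225)])
    def test_trigger_cycles_match(self, rate, expected):
        triggers = np.arange(expected) / rate
        table = segment_cycles(FS, triggers=triggers,
                               n_samples=int(300 * FS),
                               phase_source="acoustic")
        assert len(table) == expected
        durations = (table.df["end"] - table.df["start"]).to_numpy() / FS
        np.testing.assert_allclose(durations, 1.0 / rate, atol=1 / FS)

    def test_too_few_cycles_is_insufficient_data(self):
        with pytest.raises(ValueError, match="insufficient"):
            segment_cycles(FS, phase=_phase_series(1.0, 0.5))

    def test_requires_exactly_one_input(self):
        with pytest.raises(ValueError):
            segment_cycles(FS)

    def test_cycles_ordered_and_non_overlapping(self):
        table = segment_cycles(FS, phase=_phase_series(1.0, 60.0))
        df = table.df
        assert (df["end"] > df["start"]).all()
        assert (df["start"].to_numpy()[1:] >= df["end"].to_numpy()[:-1]).all()


class TestOutlierRejection:
    def _uniform_table(self, n_cycles=50):
        return segment_cycles(FS, phase=_phase_series(1.0, float(n_cycles)))

    def test_equal_power_cycles_none_rejected(self):
        # IQR = 0: the strict inequality keeps everything
        table = self._uniform_table()
        out = reject_outlier_cycles(table, np.ones(int(50 * FS)))
        assert out.n_retained == len(table)

    def test_single_boosted_cycle_is_the_only_rejection(self):
        table = self._uniform_table()
        rng = np.random.default_rng(0)
        amp = 1.0 + 0.01 * rng.standard_normal(int(50 * FS))
        s, e = table.df.loc[20, ["start", "end"]]
        amp[s:e] *= np.sqrt(10.0)
        out = reject_outlier_cycles(table, amp)
        rejected = np.flatnonzero(~out.df["retained"].to_numpy())
        assert list(rejected) == [20]
        assert out.df.loc[20, "reject_reason"] == "outlier power"

    def test_single_pass_matches_brute_force_oracle(self):
        # rejection is not recomputed on the retained set
        table = self._uniform_table()
        rng = np.random.default_rng(1)
        amp = np.abs(1.0 + rng.standard_normal(int(50 * FS)))
        out = reject_outlier_cycles(table, amp)
        powers = np.array([np.mean(amp[s:e] ** 2)
                           for s, e in zip(table.df["start"], table.df["end"])])
        q75, q25 = np.percentile(powers, [75, 25])
        expected = powers > np.median(powers) + 2 * (q75 - q25)
        np.testing.assert_array_equal(~out.df["retained"].to_numpy(), expected)

    def test_literal_rule_variant(self):
        table = self._uniform_table()
        rng = np.random.default_rng(2)
        amp = np.abs(1.0 + rng.standard_normal(int(50 * FS)))
        out = reject_outlier_cycles(table, amp, rule="2iqr")
        powers = out.df["mean_hf_power"].to_numpy()
        q75, q25 = np.percentile(powers, [75, 25])
        np.testing.assert_array_equal(~out.df["retained"].to_numpy(),
                                      powers > 2 * (q75 - q25))


class TestAmplitudeFloor:
    def _table(self, duration=50.0):
        return segment_cycles(FS, phase=_phase_series(1.0, duration))

    def test_high_amplitude_everywhere_keeps_all(self):
        table = self._table()
        out = amplitude_floor_filter(table, np.full(int(50 * FS), 200.0))
        assert out.n_retained == len(table)

    def test_low_amplitude_cycles_flagged_exactly(self):
        table = self._table()
        so = np.full(int(50 * FS), 200.0)
        for i in range(0, len(table), 2):
            s, e = table.df.loc[i, ["start", "end"]]
            so[s:e] = 30.0
        out = amplitude_floor_filter(table, so)
        flagged = ~out.df["retained"].to_numpy()
        np.testing.assert_array_equal(flagged,
                                      np.arange(len(table)) % 2 == 0)
        assert set(out.df.loc[flagged, "reject_reason"]) == {"low SO amplitude"}

    def test_zero_floor_flags_nothing(self):
        table = self._table()
        out = amplitude_floor_filter(table, np.zeros(int(50 * FS)) + 1e-9,
                                     floor=0.0)
        assert out.n_retained == len(table)

    def test_not_applicable_to_stimulation_cycles(self):
        table = segment_cycles(FS, phase=_phase_series(1.0, 50.0),
                               phase_source="tacs")
        with pytest.raises(ValueError, match="endogenous"):
            amplitude_floor_filter(table, np.full(int(50 * FS), 200.0))


class TestEqualizePhaseHistogram:
    def test_uniform_grid_is_fixed_point(self):
        grid = wrap_degrees(np.linspace(-180.0, 180.0, 73)[1:])
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(grid)
        np.testing.assert_allclose(equalize_phase_histogram(shuffled),
                                   shuffled, atol=1e-9)

    def test_circular_rank_order_preserved(self):
        # order around the circle, starting from the smallest input phase,
        # is unchanged (the output may wrap past +180)
        rng = np.random.default_rng(1)
        phases = wrap_degrees(20.0 * rng.standard_normal(500))
        out = equalize_phase_histogram(phases)
        anchor = phases.min()
        rel_in = (phases - anchor) % 360.0
        rel_out = (out - anchor) % 360.0
        assert np.array_equal(np.argsort(rel_in, kind="stable"),
                              np.argsort(rel_out, kind="stable"))

    def test_concentrated_phases_become_uniform(self):
        # von-Mises-like concentration in, circular-uniform out
        for seed in range(20):
            rng = np.random.default_rng(seed)
            phases = np.degrees(rng.vonmises(0.5, 2.0, size=400))
            out = equalize_phase_histogram(phases)
            _, p = rayleigh_test(out)
            assert p > 0.05


class TestModulationIndex:
    def test_uniform_phase_constant_amplitude_gives_near_zero(self):
        n = 10000
        phases = wrap_degrees(np.arange(n) * 360.0 / n)
        r, _ = modulation_index(np.ones(n), phases)
        assert r < 3.0 / np.sqrt(n)

    def test_cosine_modulated_amplitude_analytic_value(self):
        # A = 1 + cos(phi - 40 deg), phi uniform: <A e^{i phi}> = e^{i 40}/2
        n = 100000
        phases = wrap_degrees(np.arange(n) * 360.0 / n)
        amp = 1.0 + np.cos(np.radians(phases - 40.0))
        r, pref = modulation_index(amp, phases)
        assert abs(r - 0.5) < 1e-6
        assert abs(pref - 40.0) < 1e-6

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        amp = rng.gamma(2.0, size=1000)
        phases = rng.uniform(-180.0, 180.0, size=1000)
        r, pref = modulation_index(amp, phases)
        brute = np.sum(amp * np.exp(1j * np.radians(phases))) / 1000
        assert abs(r - np.abs(brute)) < 1e-12
        assert abs(wrap_degrees(pref - np.degrees(np.angle(brute)))) < 1e-10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            modulation_index(np.array([]), np.array([]))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(-179.0, 179.0), st.floats(0.1, 50.0))
    def test_rotation_and_scaling_invariances(self, delta, scale):
        rng = np.random.default_rng(7)
        amp = rng.gamma(2.0, size=300)
        phases = rng.uniform(-180.0, 180.0, size=300)
        r0, p0 = modulation_index(amp, phases)
        r1, p1 = modulation_index(amp, wrap_degrees(phases + delta))
        assert abs(r1 - r0) < 1e-9
        assert abs(wrap_degrees(p1 - p0 - delta)) < 1e-6
        r2, _ = modulation_index(scale * amp, phases)
        assert abs(r2 - scale * r0) < 1e-9 * max(scale, 1.0)
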