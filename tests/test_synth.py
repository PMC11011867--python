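import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitcalc.protocol import SECRETAGOGUES, default_protocol
from pitcalc.synth import (
    CellGroundTruth,
    PopulationSpec,
    TruncationWarning,
    _bleach_curve,
    largest_remainder,
    render_transient,
    sample_population,
    simulate_recording,
)


class TestLargestRemainder:
    def test_reported_tumor2_category_counts_exact(self):
        counts = largest_remainder([0.270, 0.159, 0.571], 1000)
        assert counts.tolist() == [270, 159, 571]

    @given(
        n=st.integers(1, 2000),
        raw=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_allocation_sums_to_n_and_is_near_exact(self, n, raw):
        f = np.array(raw) / np.sum(raw)
        counts = largest_remainder(f, n)
        assert counts.sum() == n
        assert np.all(np.abs(counts - f * n) < 1.0 + 1e-9)


class TestSamplePopulation:
    def test_category_counts_match_allocation_exactly(self):
        spec = PopulationSpec(
            n_cells=1000, frac_non_responsive=0.270, frac_mono=0.159, frac_multi=0.571, seed=3
        )
        cells = sample_population(spec)
        cats = [c.category for c in cells]
        assert cats.count("non_responsive") == 270
        assert cats.count("mono_responsive") == 159
        assert cats.count("multi_responsive") == 571

    def test_all_non_responsive_population(self):
        spec = PopulationSpec(n_cells=10, frac_non_responsive=1.0, seed=0)
        assert all(c.responds_to == frozenset() for c in sample_population(spec))

    def test_spontaneous_event_counts_match_uniform_1_to_12(self):
        """Uniform over 1..12 has mean 6.5; the realized mean over 50
        spontaneous cells should land within sampling error of it."""
        spec = PopulationSpec(n_cells=200, frac_spontaneous=0.25, seed=11)
        cells = sample_population(spec)
        counts = [c.n_spontaneous_events for c in cells if c.spontaneous]
        assert len(counts) == 50
        assert all(1 <= k <= 12 for k in counts)
        assert abs(np.mean(counts) - 6.5) < 1.5  # 3 x SE of uniform(1..12) mean

    def test_mono_and_multi_stimulus_counts(self):
        spec = PopulationSpec(
            n_cells=300, frac_non_responsive=0.2, frac_mono=0.4, frac_multi=0.4, seed=5
        )
        for c in sample_population(spec):
            if c.category == "mono_responsive":
                assert len(c.responds_to) == 1
            elif c.category == "multi_responsive":
                assert 2 <= len(c.responds_to) <= 5

    @given(
        n=st.integers(1, 500),
        raw=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3).filter(lambda r: sum(r) > 0.05),
        spont=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_label_counts_always_match_allocation(self, n, raw, spont, seed):
        f = np.array(raw) / np.sum(raw)
        spec = PopulationSpec(
            n_cells=n,
            frac_spontaneous=spont,
            frac_non_responsive=float(f[0]),
            frac_mono=float(f[1]),
            frac_multi=float(f[2]),
            seed=seed,
        )
        cells = sample_population(spec)
        expected = largest_remainder(f, n)
        cats = [c.category for c in cells]
        assert [
            cats.count("non_responsive"),
            cats.count("mono_responsive"),
            cats.count("multi_responsive"),
        ] == expected.tolist()
        n_spont = largest_remainder([spont, 1 - spont], n)[0]
        assert sum(c.spontaneous for c in cells) == n_spont

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(n_cells=10, frac_non_responsive=0.5, frac_mono=0.2, frac_multi=0.2)
        with pytest.raises(ValueError):
            PopulationSpec(n_cells=10, frac_spontaneous=1.5)


class TestRenderTransient:
    def test_fast_kernel_peak_and_return_to_rest(self):
        seg = render_transient("fast", 1.0, 0.0, 0.2, 10.0)
        assert seg.max() == pytest.approx(1.0, abs=0.01)
        t = np.arange(len(seg)) * 0.2
        assert np.all(seg[t >= 5.0] < 0.05)
        assert np.all(seg >= 0)

    def test_prolonged_kernel_fwhm_at_least_20s(self):
        with pytest.warns(TruncationWarning):
            seg = render_transient("prolonged", 0.5, 0.0, 0.2, 60.0)
        above_half = np.flatnonzero(seg >= 0.25)
        fwhm = (above_half[-1] - above_half[0]) * 0.2
        assert fwhm >= 20.0

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            render_transient("fast", 0.0, 0.0, 0.2, 10.0)

    def test_truncation_is_reported_not_silent(self):
        with pytest.warns(TruncationWarning):
            render_transient("fast", 1.0, 0.0, 0.2, 1.0)


class TestSimulateRecording:
    def test_pure_bleach_outside_high_k_when_no_signal_no_noise(self, tiny_protocol):
        spec = PopulationSpec(n_cells=5, noise_sd=0.0, bleach_depth=0.3, seed=2)
        rec = simulate_recording(spec, tiny_protocol)
        t = rec.frame_times
        bleach = _bleach_curve(t, 0.3, spec.bleach_tau_s, tiny_protocol.total_duration_s)
        before_hk = t < tiny_protocol.high_k.start_s
        for ci in range(5):
            f0 = rec.fluorescence[ci, 0] / bleach[0]
            np.testing.assert_allclose(rec.fluorescence[ci, before_hk], f0 * bleach[before_hk], rtol=1e-12)

    def test_spontaneous_cell_count_by_largest_remainder(self, tiny_protocol):
        spec = PopulationSpec(n_cells=100, frac_spontaneous=0.574, seed=4)
        rec = simulate_recording(spec, tiny_protocol)
        carriers = [c for c in rec.ground_truth if len(c.baseline_event_onsets_s) >= 1]
        assert len(carriers) == 57

    def test_noise_sd_matches_requested_level(self, tiny_protocol):
        spec = PopulationSpec(n_cells=50, noise_sd=0.05, bleach_depth=0.2, seed=6)
        rec = simulate_recording(spec, tiny_protocol)
        t = rec.frame_times
        bleach = _bleach_curve(t, 0.2, spec.bleach_tau_s, tiny_protocol.total_duration_s)
        before_hk = t < tiny_protocol.high_k.start_s
        resid_sd = []
        for ci in range(50):
            detrended = rec.fluorescence[ci] / bleach
            f0 = np.median(detrended[before_hk])
            resid_sd.append(np.std(detrended[before_hk] / f0 - 1.0))
        assert np.mean(resid_sd) == pytest.approx(0.05, rel=0.05)

    def test_same_seed_bit_identical_different_seed_same_counts(self, tiny_protocol):
        spec = PopulationSpec(n_cells=20, frac_spontaneous=0.5, noise_sd=0.02, seed=9)
        a = simulate_recording(spec, tiny_protocol)
        b = simulate_recording(spec, tiny_protocol)
        np.testing.assert_array_equal(a.fluorescence, b.fluorescence)
        import dataclasses

        c = simulate_recording(dataclasses.replace(spec, seed=10), tiny_protocol)
        assert not np.array_equal(a.fluorescence, c.fluorescence)
        assert sum(x.spontaneous for x in a.ground_truth) == sum(x.spontaneous for x in c.ground_truth)
        onsets_a = [x.baseline_event_onsets_s for x in a.ground_truth if x.spontaneous]
        onsets_c = [x.baseline_event_onsets_s for x in c.ground_truth if x.spontaneous]
        assert onsets_a != onsets_c

    def test_no_transient_outside_designated_epoch(self, compressed_protocol):
        """Noiseless, bleach-free simulation: baseline events are silent
        from the first pulse on; responses are silent before their pulse
        and from the next pulse on."""
        spec = PopulationSpec(
            n_cells=40,
            frac_spontaneous=0.5,
            frac_non_responsive=0.2,
            frac_mono=0.4,
            frac_multi=0.4,
            noise_sd=0.0,
            bleach_depth=0.0,
            seed=13,
        )
        rec = simulate_recording(spec, compressed_protocol)
        t = rec.frame_times
        first_pulse = compressed_protocol.stimuli[0].start_s
        for ci, cell in enumerate(rec.ground_truth):
            f0 = rec.fluorescence[ci, 0]
            dff = rec.fluorescence[ci] / f0 - 1.0
            # baseline events never leak past the first pulse
            if not cell.responds_to:
                sl = (t >= first_pulse) & (t < compressed_protocol.high_k.start_s)
                assert np.all(np.abs(dff[sl]) < 1e-9)
            # a pulse the cell ignores stays silent: any earlier response is
            # truncated at this pulse's start
            for stim in compressed_protocol.stimuli:
                if stim.label not in cell.responds_to:
                    span = (t >= stim.start_s) & (t < stim.end_s)
                    assert np.all(np.abs(dff[span]) < 1e-9)
                    assert stim.label not in cell.response_onsets_s

    def test_signal_is_exact_kernel_sum_when_clean(self, tiny_protocol):
        """With zero noise and zero bleach the ΔF/F trace equals the sum of
        its transient kernels exactly."""
        from pitcalc.synth import KERNEL_TAUS, _kernel

        spec = PopulationSpec(n_cells=10, frac_spontaneous=1.0, noise_sd=0.0, bleach_depth=0.0, seed=21)
        rec = simulate_recording(spec, tiny_protocol)
        t = rec.frame_times
        base_end = tiny_protocol.baseline.end_s
        for ci, cell in enumerate(rec.ground_truth):
            f0 = rec.fluorescence[ci, 0]
            dff = rec.fluorescence[ci] / f0 - 1.0
            expected = np.zeros_like(dff)
            tau_r, tau_d = KERNEL_TAUS[cell.shape_class]
            for onset in cell.baseline_event_onsets_s:
                m = (t >= onset) & (t < base_end)
                expected[m] += spec.spont_amplitude * cell.amplitude_scale * _kernel(t[m] - onset, tau_r, tau_d)
            in_baseline = t < base_end
            np.testing.assert_allclose(dff[in_baseline], expected[in_baseline], atol=1e-9)

    def test_protocol_without_high_k_rejected(self):
        from pitcalc.protocol import Epoch, StimulusProtocol

        with pytest.raises(Exception):
            bad = StimulusProtocol(0.2, (Epoch("baseline", 0.0, 10.0),), 10.0)
            simulate_recording(PopulationSpec(n_cells=2), bad)

    def test_ground_truth_invariants(self):
        with pytest.raises(ValueError):
            CellGroundTruth(viable=False, spontaneous=True, n_spontaneous_events=2, responds_to=frozenset())
        with pytest.raises(ValueError):
            CellGroundTruth(viable=True, spontaneous=True, n_spontaneous_events=0, responds_to=frozenset())
        with pytest.raises(ValueError):
            CellGroundTruth(viable=True, spontaneous=False, n_spontaneous_events=0, responds_to=frozenset(["XXX"]))
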