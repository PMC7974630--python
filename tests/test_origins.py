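import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from puseq import (
    DifferentialSignal,
    GenomeLayout,
    Origin,
    ReplicationProgram,
    call_origins,
    combine_differentials,
    detect_peaks,
    differentiate,
    filter_peaks,
    normalise_efficiencies,
    origins_from_tracks,
    simulate_population,
    sma,
)

from conftest import make_track, tracks_from_f_right
from oracles import brute_force_peaks


def signal_from(values, *extra_chroms):
    """Wrap raw per-bin vectors into a DifferentialSignal on a matching layout."""
    chroms = [("chrI", len(values) * 300)]
    data = {"chrI": np.asarray(values, dtype=float)}
    for i, v in enumerate(extra_chroms):
        name = f"chr{'II' * (i + 1)}"
        chroms.append((name, len(v) * 300))
        data[name] = np.asarray(v, dtype=float)
    return DifferentialSignal(GenomeLayout(tuple(chroms), 300), data)


class TestDifferentiate:
    def test_matches_manual_smooth_then_diff(self):
        lay = GenomeLayout((("chrI", 6 * 300),), 300)
        raw = [0.0, 0.1, 0.5, 0.4, -0.2, -0.3]
        track = make_track(lay, "epsilon", {"chrI": raw})
        diff = differentiate(track)["chrI"]
        smoothed = sma(raw, 3)
        assert diff[0] == 0.0
        np.testing.assert_allclose(diff[1:], np.diff(smoothed))

    def test_constant_track_gives_zeros(self):
        lay = GenomeLayout((("chrI", 5 * 300),), 300)
        track = make_track(lay, "delta", {"chrI": [0.4] * 5})
        np.testing.assert_allclose(differentiate(track)["chrI"], 0.0, atol=1e-15)

    def test_first_bin_zero_on_every_chromosome(self):
        lay = GenomeLayout((("chrI", 4 * 300), ("chrII", 3 * 300)), 300)
        track = make_track(
            lay, "epsilon", {"chrI": [0.9, -0.9, 0.9, -0.9], "chrII": [-1.0, 1.0, -1.0]}
        )
        diff = differentiate(track)
        assert diff["chrI"][0] == 0.0
        assert diff["chrII"][0] == 0.0  # no carry-over from chrI's last bin


class TestCombineDifferentials:
    def _combine_flat(self, e, d, a):
        # constant differential vectors so the trailing SMA changes nothing
        lay = GenomeLayout((("chrI", 3 * 300),), 300)
        out = combine_differentials(
            {"chrI": np.full(3, e)}, {"chrI": np.full(3, d)}, {"chrI": np.full(3, a)}, lay
        )
        return out.values["chrI"][1]

    def test_opposite_lagging_signs_average(self):
        assert self._combine_flat(0.3, -0.3, -0.3) == pytest.approx(0.3)

    def test_unequal_contributions(self):
        assert self._combine_flat(0.3, -0.1, -0.2) == pytest.approx(0.2)

    def test_all_zero(self):
        assert self._combine_flat(0.0, 0.0, 0.0) == 0.0

    def test_length_mismatch_rejected(self):
        lay = GenomeLayout((("chrI", 3 * 300),), 300)
        with pytest.raises(ValueError, match="mismatch"):
            combine_differentials(
                {"chrI": np.zeros(3)}, {"chrI": np.zeros(2)}, {"chrI": np.zeros(3)}, lay
            )


class TestDetectPeaks:
    def test_single_positive_run(self):
        peaks = detect_peaks(signal_from([-0.1, 0.2, 0.5, 0.1, -0.2]))
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start_bin, p.end_bin, p.max_bin) == (1, 3, 2)
        assert p.max_value == pytest.approx(0.5)
        assert p.sum_values == pytest.approx(0.8)

    def test_distant_maxima_split_at_run_minimum(self):
        peaks = detect_peaks(signal_from([0.1, 0.5, 0.1, 0.05, 0.1, 0.6, 0.1]))
        assert len(peaks) == 2
        left, right = peaks
        assert (left.start_bin, left.end_bin) == (0, 3)  # minimum bin 3 goes left
        assert (right.start_bin, right.end_bin) == (4, 6)
        assert left.sum_values + right.sum_values == pytest.approx(sum([0.1, 0.5, 0.1, 0.05, 0.1, 0.6, 0.1]))

    def test_close_maxima_stay_one_peak(self):
        peaks = detect_peaks(signal_from([0.1, 0.5, 0.1, 0.6, 0.1]))
        assert len(peaks) == 1

    def test_all_negative_gives_no_peaks(self):
        assert detect_peaks(signal_from([-0.3, -0.1, -0.5])) == []

    @given(
        st.lists(
            st.integers(-100, 100).map(lambda x: x / 100.0),
            min_size=1, max_size=30,
        )
    )
    @settings(max_examples=300, derandomize=True)
    def test_agrees_with_brute_force(self, values):
        got = detect_peaks(signal_from(values))
        want = brute_force_peaks(values)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert (g.start_bin, g.end_bin, g.max_bin) == (w["start"], w["end"], w["max_bin"])
            assert g.max_value == pytest.approx(w["max_value"], abs=1e-12)
            assert g.sum_values == pytest.approx(w["sum"], abs=1e-12)

    def test_split_conserves_sum(self):
        rng = np.random.default_rng(0)
        v = np.abs(rng.normal(0.3, 0.2, 25)) + 0.01  # one long all-positive run
        peaks = detect_peaks(signal_from(v))
        assert sum(p.sum_values for p in peaks) == pytest.approx(v.sum())


class TestFilterPeaks:
    def _peaks(self, maxima):
        return detect_peaks(
            signal_from(
                np.concatenate([[0.0, m, 0.0] for m in maxima])
            )
        )

    def test_percentile_threshold_interpolates(self):
        peaks = self._peaks(range(1, 11))
        kept = filter_peaks(peaks, 30)
        # 30th percentile of 1..10 is 3.7 -> maxima 4..10 survive
        assert sorted(p.max_value for p in kept) == list(range(4, 11))

    def test_percentile_zero_keeps_all(self):
        peaks = self._peaks([0.5, 1.0, 2.0])
        assert len(filter_peaks(peaks, 0)) == 3

    def test_all_equal_maxima_all_kept(self):
        peaks = self._peaks([1.0, 1.0, 1.0])
        assert len(filter_peaks(peaks, 30)) == 3

    def test_empty_input_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert filter_peaks([], 30) == []
        assert any("no candidate" in r.message for r in caplog.records)


class TestCallOrigins:
    def test_efficiency_is_half_peak_sum(self):
        calls = call_origins(signal_from([-0.1, 0.2, 0.4, 0.2, -0.1]))
        assert len(calls) == 1
        assert calls[0].efficiency_raw == pytest.approx(0.4)
        assert calls[0].origin_bin == 2

    def test_all_negative_signal_gives_no_origins(self):
        assert call_origins(signal_from([-0.2, -0.1, -0.3])) == []

    def test_sorted_by_chrom_then_bin(self):
        sig = signal_from([0, 0.5, 0, 0, 0, 0.3, 0], [0, 0.4, 0])
        calls = call_origins(sig, percentile=0)
        assert [(c.chrom, c.origin_bin) for c in calls] == [
            ("chrI", 1), ("chrI", 5), ("chrII", 1)
        ]


class TestNormaliseEfficiencies:
    def test_scaling(self):
        calls = call_origins(
            signal_from([0, 1.0, 0, 0, 0.8, 0, 0, 0.5, 0]), percentile=0
        )
        normed = normalise_efficiencies(calls)
        assert [o.efficiency_norm for o in normed] == pytest.approx([100, 80, 50])

    def test_single_origin_is_100(self):
        normed = normalise_efficiencies(call_origins(signal_from([0, 0.3, 0])))
        assert normed[0].efficiency_norm == 100.0

    def test_equal_origins_both_100(self):
        normed = normalise_efficiencies(
            call_origins(signal_from([0, 0.4, 0, 0, 0.4, 0]), percentile=0)
        )
        assert [o.efficiency_norm for o in normed] == [100.0, 100.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalise_efficiencies([])


def _three_origin_program(shift=0, middle_p=0.6, n_bins=400):
    lay = GenomeLayout((("chrI", n_bins * 300),), 300)
    return ReplicationProgram(
        lay,
        (
            Origin("chrI", 80 + shift, 0.9, 1.0),
            Origin("chrI", 190 + shift, middle_p, 1.0),
            Origin("chrI", 310 + shift, 0.8, 1.0),
        ),
        fork_speed=10.0,
    )


def _call_noise_free(program, seed=21, n_cells=3000):
    prof = simulate_population(program, n_cells, seed)
    tracks = tracks_from_f_right(program.layout, prof.f_right)
    return prof, origins_from_tracks(tracks)


class TestPipelineInvariants:
    def test_shift_invariance(self):
        _, calls0 = _call_noise_free(_three_origin_program(shift=0))
        _, calls7 = _call_noise_free(_three_origin_program(shift=7))
        pos0 = [c.origin_bin for c in calls0]
        pos7 = [c.origin_bin for c in calls7]
        assert [p + 7 for p in pos0] == pos7
        np.testing.assert_allclose(
            [c.efficiency_raw for c in calls0],
            [c.efficiency_raw for c in calls7],
            atol=1e-9,
        )

    def test_mirror_symmetry(self):
        prog = _three_origin_program()
        prof = simulate_population(prog, 3000, seed=21)
        n = prog.layout.n_bins("chrI")
        f = prof.f_right["chrI"]
        fwd = origins_from_tracks(tracks_from_f_right(prog.layout, {"chrI": f}))
        mirrored_f = 1.0 - f[::-1]
        rev = origins_from_tracks(tracks_from_f_right(prog.layout, {"chrI": mirrored_f}))
        assert len(fwd) == len(rev)
        # a differential at bin i measures the edge between bins i-1 and i,
        # so the mirror maps an origin at m to n-m (within one bin)
        for o_f, o_r in zip(fwd, reversed(rev)):
            assert abs(o_r.origin_bin - (n - o_f.origin_bin)) <= 1
            assert o_r.efficiency_raw == pytest.approx(o_f.efficiency_raw, abs=1e-9)

    def test_monotone_in_firing_probability(self):
        # percentile=0: the filter is not part of the estimator under test,
        # and with only three clean candidate peaks it would drop the weakest
        effs = []
        for p in (0.3, 0.5, 0.7, 0.9):
            prog = _three_origin_program(middle_p=p)
            prof = simulate_population(prog, 3000, 21)
            tracks = tracks_from_f_right(prog.layout, prof.f_right)
            calls = origins_from_tracks(tracks, percentile=0)
            near = [c for c in calls if abs(c.origin_bin - 190) <= 5]
            effs.append(max(c.efficiency_raw for c in near))
        assert effs == sorted(effs)
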