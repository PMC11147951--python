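"""Interval parsing, anchors, meta-profiles, quantile bins, DHS counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfscore.intervals_profiles import (Interval, IntervalSet, anchors,
                                        dhs_score, mean_profile,
                                        quantile_split, read_intervals,
                                        strand_flipped)
from nfscore.synthetic import gen_peak_panel
from nfscore.track import GenomeTrack


def make_track(**arrays):
    return GenomeTrack(data={k: np.asarray(v, float) for k, v in arrays.items()})


class TestReadIntervals:
    def test_narrowpeak_summit_offset(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t1000\t1500\tpk1\t0\t.\t5.0\t-1\t-1\t75\n")
        ivs = read_intervals(path)
        assert ivs[0].point_source_offset == 75
        assert anchors(ivs, "point_source")[0] == 1075

    def test_summit_minus_one_falls_back_to_midpoint(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t1000\t1500\tpk1\t0\t.\t5.0\t-1\t-1\t-1\n")
        ivs = read_intervals(path)
        assert ivs[0].point_source_offset is None
        with pytest.raises(ValueError, match="point-source"):
            anchors(ivs, "point_source")
        assert anchors(ivs, "point_source", point_source_fallback=True)[0] == 1250

    def test_bed6_strand_preserved(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr2\t10\t50\tx\t0\t-\n")
        assert read_intervals(path)[0].strand == "-"

    def test_end_not_after_start_reports_line(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t5\t10\nchr1\t30\t30\n")
        with pytest.raises(ValueError, match=":2.*start >= end"):
            read_intervals(path)

    def test_unrecognized_column_count(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t5\t10\tx\t0\t+\textra\n")
        with pytest.raises(ValueError, match="column count"):
            read_intervals(path)


class TestAnchors:
    def test_midpoint_floor_convention(self):
        ivs = IntervalSet([Interval("chr1", 100, 229, strand="+")])
        assert anchors(ivs, "midpoint")[0] == 164  # 100 + 129 // 2

    def test_five_prime_on_minus_strand(self):
        ivs = IntervalSet([Interval("chr1", 5000, 8000, strand="-")])
        assert anchors(ivs, "five_prime")[0] == 7999

    def test_junction_is_five_prime_boundary(self):
        ivs = IntervalSet([Interval("chr1", 300, 450, strand="+"),
                           Interval("chr1", 300, 450, strand="-")])
        assert np.array_equal(anchors(ivs, "junction"),
                              anchors(ivs, "five_prime"))


class TestMeanProfile:
    def test_constant_track_flat_profile(self):
        track = make_track(chr1=np.full(1000, 2.5))
        ivs = IntervalSet([Interval("chr1", 400, 500, strand="+")])
        prof = mean_profile(track, ivs, "midpoint", flank=50)
        assert np.allclose(prof.mean, 2.5)
        assert (prof.n == 1).all()

    def test_minus_strand_reverses_ramp(self):
        ramp = np.arange(1000, dtype=float)
        track = make_track(chr1=ramp)
        iv = Interval("chr1", 400, 501, strand="-")
        prof = mean_profile(track, IntervalSet([iv]), "midpoint", flank=20)
        a = 400 + 101 // 2
        expect = ramp[a - 20:a + 21][::-1]
        assert np.array_equal(prof.mean, expect)

    def test_two_interval_average(self):
        track = make_track(chr1=np.r_[np.full(500, 1.0), np.full(500, 3.0)])
        ivs = IntervalSet([Interval("chr1", 200, 201, strand="+"),
                           Interval("chr1", 700, 701, strand="+")])
        prof = mean_profile(track, ivs, "midpoint", flank=5)
        assert np.allclose(prof.mean, 2.0)
        assert (prof.n == 2).all()

    def test_unknown_chromosome_skipped(self, caplog):
        track = make_track(chr1=np.zeros(100))
        ivs = IntervalSet([Interval("chr1", 40, 60), Interval("chrUn", 40, 60)])
        with caplog.at_level("WARNING"):
            prof = mean_profile(track, ivs, "midpoint", flank=5)
        assert (prof.n == 1).all()
        assert "skipped 1" in caplog.text

    def test_out_of_range_offsets_are_gaps(self):
        track = make_track(chr1=np.ones(100))
        ivs = IntervalSet([Interval("chr1", 0, 1, strand="+")])
        prof = mean_profile(track, ivs, "midpoint", flank=10)
        assert (prof.n[:10] == 0).all() and np.isnan(prof.mean[:10]).all()
        assert (prof.n[10:] == 1).all()

    def test_strand_balanced_set_symmetric_on_symmetric_track(self):
        """Averaging +/- pairs over a mirror-symmetric track gives a
        profile symmetric about the anchor."""
        n = 2001
        sym = np.abs(np.arange(n) - 1000).astype(float)  # V shape, even
        track = make_track(chr1=sym)
        ivs = [Interval("chr1", 995, 1006, strand=s) for s in "+-"]
        prof = mean_profile(track, IntervalSet(ivs), "midpoint", flank=100)
        assert np.allclose(prof.mean, prof.mean[::-1])

    def test_no_intervals_rejected(self):
        with pytest.raises(ValueError, match="no intervals"):
            mean_profile(make_track(chr1=np.ones(10)), IntervalSet([]),
                         "midpoint", flank=2)


class TestQuantileSplit:
    def test_exact_quartering(self):
        ivs = IntervalSet([Interval("c", 0, n) for n in range(1, 9)])
        groups = quantile_split(ivs, 4)
        assert [sorted(len(iv) for iv in g) for g in groups] == [
            [1, 2], [3, 4], [5, 6], [7, 8]]

    def test_remainder_goes_to_early_groups(self):
        ivs = IntervalSet([Interval("c", 0, n) for n in (5, 1, 4, 2, 3)])
        sizes = [len(g) for g in quantile_split(ivs, 4)]
        assert sizes == [2, 1, 1, 1]

    def test_equal_lengths_preserve_input_order(self):
        ivs = IntervalSet([Interval("c", i, i + 10, name=f"iv{i}")
                           for i in range(6)])
        groups = quantile_split(ivs, 3)
        names = [iv.name for g in groups for iv in g]
        assert names == [f"iv{i}" for i in range(6)]

    @given(n=st.integers(min_value=4, max_value=40),
           q=st.integers(min_value=2, max_value=6))
    @settings(max_examples=40, deadline=None)
    def test_partition_no_loss_no_duplication(self, n, q):
        if n < q:
            n = q
        rng = np.random.default_rng(n * 7 + q)
        ivs = IntervalSet([
            Interval("c", int(s), int(s) + int(rng.integers(1, 50)),
                     name=f"iv{i}")
            for i, s in enumerate(rng.integers(0, 1000, size=n))])
        groups = quantile_split(ivs, q)
        names = sorted(iv.name for g in groups for iv in g)
        assert names == sorted(iv.name for iv in ivs)
        assert sum(len(g) for g in groups) == n
        assert g_sizes_near_equal([len(g) for g in groups])

    def test_too_few_intervals(self):
        with pytest.raises(ValueError, match="cannot split"):
            quantile_split(IntervalSet([Interval("c", 0, 5)]), 4)


def g_sizes_near_equal(sizes):
    return max(sizes) - min(sizes) <= 1


class TestDhsScore:
    def test_worked_examples_403_and_5(self, tmp_path):
        """A bp covered in all 403 files scores 403; in 5 files, 5."""
        for n_cov, sub in ((403, "all"), (5, "five")):
            paths = gen_peak_panel(403, 60_000, n_cov, tmp_path / sub, seed=1)
            track = dhs_score(paths)
            assert track.data["chr1"][60_000] == n_cov

    def test_zero_covering(self, tmp_path):
        paths = gen_peak_panel(20, 5_000, 0, tmp_path / "none", seed=2)
        track = dhs_score(paths)
        assert track.data["chr1"][5_000] == 0

    def test_overlapping_peaks_in_one_file_count_once(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t100\t200\nchr1\t150\t250\n")
        track = dhs_score([path])
        assert track.data["chr1"][160] == 1

    def test_matches_brute_force_membership(self, tmp_path):
        rng = np.random.default_rng(3)
        paths = []
        spans = []
        for i in range(6):
            p = tmp_path / f"f{i}.bed"
            rows = [(int(s), int(s) + int(rng.integers(5, 40)))
                    for s in rng.integers(0, 400, size=4)]
            p.write_text("".join(f"chrT\t{s}\t{e}\n" for s, e in rows))
            paths.append(p)
            spans.append(rows)
        track = dhs_score(paths)
        arr = track.data["chrT"]
        for bp in range(0, arr.size, 13):
            brute = sum(any(s <= bp < e for s, e in rows) for rows in spans)
            assert arr[bp] == brute
        assert arr.max() <= 6 and arr.min() >= 0

    def test_unreadable_file_aborts_with_name(self, tmp_path):
        with pytest.raises(OSError, match="nope.bed"):
            dhs_score([tmp_path / "nope.bed"])

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            dhs_score([])


def test_strand_flipped_involution():
    ivs = IntervalSet([Interval("c", 0, 10, strand="+"),
                       Interval("c", 5, 15, strand="-"),
                       Interval("c", 8, 20, strand=".")])
    twice = strand_flipped(strand_flipped(ivs))
    assert [iv.strand for iv in twice] == [iv.strand for iv in ivs]
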