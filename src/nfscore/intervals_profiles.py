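"""Genomic intervals, strand-aware meta-profiles, and the DHS peak count.

All coordinates are 0-based half-open, matching BED bit-exactly; narrowPeak
summit offsets (column 10) are added to ``start``.  Meta-profiles are always
oriented 5'->3': the values extracted around a minus-strand anchor are
reversed before aggregation, and strand "." is treated as "+" (the usual
case for orientation-free peak inputs) with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .track import GenomeTrack

logger = logging.getLogger(__name__)

ANCHOR_MODES = ("point_source", "midpoint", "five_prime", "junction")


@dataclass
class Interval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    point_source_offset: int | None = None
    cluster: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"start >= end: {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.point_source_offset is not None and not (
                0 <= self.point_source_offset < self.end - self.start):
            raise ValueError("point_source_offset outside interval")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    """An ordered collection of intervals, optionally labeled (e.g. a length bin)."""

    intervals: list
    label: str = ""
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def lengths(self) -> np.ndarray:
        return np.array([len(iv) for iv in self.intervals], dtype=int)


def read_intervals(path) -> IntervalSet:
    """Read BED3/BED6 or narrowPeak (10 columns) intervals.

    narrowPeak column 10 becomes the point-source (summit) offset; the
    sentinel -1 is stored as "no offset" so that anchoring can fall back to
    the midpoint.  Malformed coordinates are reported with their line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4, 5, 6, 10):
                raise ValueError(
                    f"{path}:{lineno}: unrecognized column count {len(parts)} "
                    f"(expected BED3/BED6 or narrowPeak-10)"
                )
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            offset = None
            if len(parts) == 10:
                peak = int(parts[9])
                if peak >= 0:
                    if peak >= end - start:
                        raise ValueError(
                            f"{path}:{lineno}: summit offset {peak} outside interval"
                        )
                    offset = peak
            intervals.append(Interval(chrom, start, end, strand=strand, name=name,
                                      point_source_offset=offset))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def anchor_position(iv: Interval, mode: str, point_source_fallback: bool = False) -> int:
    """Single anchor bp of an interval under the given mode.

    ``five_prime`` is the 5' end in transcript orientation (start on +, end-1
    on -); ``junction`` is the same position, named for exon-start semantics;
    ``midpoint`` uses the floor convention ``start + (end-start)//2``;
    ``point_source`` uses the stored summit offset, falling back to the
    midpoint only when explicitly allowed.
    """
    if mode not in ANCHOR_MODES:
        raise ValueError(f"unknown anchor mode {mode!r}")
    if mode == "point_source":
        if iv.point_source_offset is None:
            if not point_source_fallback:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} has no point-source "
                    f"offset (enable the midpoint fallback to proceed)"
                )
            return anchor_position(iv, "midpoint")
        return iv.start + iv.point_source_offset
    if mode in ("five_prime", "junction"):
        return iv.end - 1 if iv.strand == "-" else iv.start
    return iv.start + (len(iv) // 2)


def anchors(intervals: IntervalSet, mode: str,
            point_source_fallback: bool = False) -> np.ndarray:
    """Per-interval anchor positions."""
    return np.array(
        [anchor_position(iv, mode, point_source_fallback) for iv in intervals],
        dtype=int,
    )


@dataclass
class MeanProfile:
    """Per-offset mean of a track around anchors, oriented 5'->3'."""

    offsets: np.ndarray
    mean: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean, "n": self.n})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def mean_profile(track: GenomeTrack, intervals: IntervalSet, mode: str,
                 flank: int, point_source_fallback: bool = False) -> MeanProfile:
    """Average a track over anchor-centered windows, strand-aware.

    Per interval the values at ``anchor-flank .. anchor+flank`` are extracted
    and reversed for minus-strand intervals; the per-offset mean runs over
    defined values only, with ``n`` recording how many intervals contribute
    at each offset.  Intervals on chromosomes absent from the track are
    skipped with a logged count.
    """
    if len(intervals) == 0:
        raise ValueError("no intervals to profile")
    width = 2 * flank + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=int)
    skipped = 0
    unstranded = 0
    for iv in intervals:
        if iv.chrom not in track.data:
            skipped += 1
            continue
        if iv.strand == ".":
            unstranded += 1
        a = anchor_position(iv, mode, point_source_fallback)
        vals = track.get(iv.chrom, a - flank, a + flank + 1)
        if iv.strand == "-":
            vals = vals[::-1]
        ok = ~np.isnan(vals)
        total[ok] += vals[ok]
        count += ok
    if skipped:
        logger.warning("mean_profile: skipped %d intervals on chromosomes "
                       "absent from the track", skipped)
    if unstranded:
        logger.info("mean_profile: %d unstranded intervals treated as '+'",
                    unstranded)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MeanProfile(offsets=np.arange(-flank, flank + 1), mean=mean, n=count)


def quantile_split(intervals: IntervalSet, q: int) -> list:
    """Split intervals into q near-equal groups by increasing length.

    Sizes differ by at most one (the remainder goes to the shortest-length
    groups); length ties keep input order.  Each subset is labeled with its
    rank and reports its length range and median in ``stats``.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    n = len(intervals)
    if n < q:
        raise ValueError(f"cannot split {n} intervals into {q} quantile groups")
    order = sorted(range(n), key=lambda i: (len(intervals[i]), i))
    base, rem = divmod(n, q)
    sizes = [base + 1 if g < rem else base for g in range(q)]
    out = []
    pos = 0
    for g, size in enumerate(sizes):
        idx = order[pos:pos + size]
        pos += size
        ivs = [intervals[i] for i in idx]
        lens = np.array([len(iv) for iv in ivs])
        out.append(IntervalSet(
            ivs,
            label=f"q{g + 1}",
            stats={"min_length": int(lens.min()), "max_length": int(lens.max()),
                   "median_length": float(np.median(lens)), "n": len(ivs)},
        ))
    return out


def dhs_score(peak_files, lengths: dict | None = None) -> GenomeTrack:
    """Per-bp count of peak files with at least one peak overlapping that bp.

    This is the multi-sample accessibility score: over a panel of n files
    (403 DNase-seq primary cell lines in the motivating use) a base pair
    overlapped by peaks in every file scores n, one overlapped in five files
    scores 5, and uncovered base pairs score 0.  Several overlapping peaks
    within one file still count once.
    """
    if not peak_files:
        raise ValueError("at least one peak file required")
    coverage: dict[str, np.ndarray] = {}

    def _ensure(chrom, size):
        arr = coverage.get(chrom)
        if arr is None:
            arr = np.zeros(size, dtype=np.int32)
        elif arr.size < size:
            arr = np.concatenate([arr, np.zeros(size - arr.size, dtype=np.int32)])
        coverage[chrom] = arr
        return arr

    for path in peak_files:
        try:
            ivs = read_intervals(path)
        except OSError as exc:
            raise OSError(f"cannot read peak file {path}: {exc}") from exc
        per_chrom: dict[str, list] = {}
        for iv in ivs:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in per_chrom.items():
            spans.sort()
            merged = []
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((cur_s, cur_e))
            arr = _ensure(chrom, merged[-1][1])
            for s, e in merged:
                arr[s:e] += 1
    if lengths:
        for chrom, n in lengths.items():
            _ensure(chrom, n)
    data = {c: coverage[c].astype(float) for c in coverage}
    return GenomeTrack(data=data, semantics="count")


def strand_flipped(intervals: IntervalSet) -> IntervalSet:
    """Utility: the same intervals with + and - strands exchanged."""
    flipped = [replace(iv, strand={"+": "-", "-": "+", ".": "."}[iv.strand])
               for iv in intervals]
    return IntervalSet(flipped, label=intervals.label)
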