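"""Per-base genomic signal tracks with explicit gaps.

A :class:`GenomeTrack` holds one float array per reference sequence, with NaN
marking positions that carry no value (uncovered flanks, masked windows).
Gaps are explicit — they are never silently written as zero.  Tracks
round-trip through 4-column bedGraph and through bigWig.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class GenomeTrack:
    """Dense per-bp values keyed by reference name; NaN encodes a gap."""

    data: dict = field(default_factory=dict)
    semantics: str = "score"  # descriptive: e.g. low_res {0,1}, high_res [0,1], count

    @property
    def chroms(self) -> list:
        return list(self.data.keys())

    def length(self, chrom: str) -> int:
        return len(self.data[chrom])

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); positions outside the reference are NaN."""
        arr = self.data[chrom]
        out = np.full(end - start, np.nan)
        lo = max(start, 0)
        hi = min(end, arr.size)
        if hi > lo:
            out[lo - start:hi - start] = arr[lo:hi]
        return out

    def defined_fraction(self, chrom: str) -> float:
        arr = self.data[chrom]
        return float(np.mean(~np.isnan(arr))) if arr.size else 0.0

    # ---- I/O -------------------------------------------------------------

    def to_bedgraph(self, path) -> None:
        """Write as sorted, non-overlapping 4-column bedGraph, skipping gaps."""
        tmp = _temp_sibling(path)
        try:
            with open(tmp, "w") as fh:
                for chrom in sorted(self.data):
                    arr = self.data[chrom]
                    for start, end, value in _runs(arr):
                        fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    @classmethod
    def from_bedgraph(cls, path, lengths: dict | None = None,
                      semantics: str = "score") -> "GenomeTrack":
        """Read a bedGraph; array lengths default to the max end seen per chrom."""
        records: dict[str, list] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if start >= end:
                    raise ValueError(f"{path}:{lineno}: start >= end")
                records.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, recs in records.items():
            n = lengths[chrom] if lengths else max(e for _, e, _ in recs)
            arr = np.full(n, np.nan)
            for start, end, value in recs:
                arr[start:end] = value
            data[chrom] = arr
        if lengths:
            for chrom, n in lengths.items():
                data.setdefault(chrom, np.full(n, np.nan))
        return cls(data=data, semantics=semantics)

    def to_bigwig(self, path) -> None:
        import pyBigWig

        tmp = _temp_sibling(path)
        try:
            bw = pyBigWig.open(str(tmp), "w")
            chroms = sorted(self.data)
            bw.addHeader([(c, len(self.data[c])) for c in chroms])
            for chrom in chroms:
                starts, ends, values = [], [], []
                for start, end, value in _runs(self.data[chrom]):
                    starts.append(start)
                    ends.append(end)
                    values.append(float(value))
                if starts:
                    bw.addEntries([chrom] * len(starts), starts,
                                  ends=ends, values=values)
            bw.close()
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    @classmethod
    def from_bigwig(cls, path, semantics: str = "score") -> "GenomeTrack":
        import pyBigWig

        bw = pyBigWig.open(str(path))
        data = {}
        for chrom, n in bw.chroms().items():
            data[chrom] = np.asarray(bw.values(chrom, 0, n), dtype=float)
        bw.close()
        return cls(data=data, semantics=semantics)


def _runs(arr: np.ndarray):
    """Yield (start, end, value) runs of equal defined values."""
    defined = ~np.isnan(arr)
    if not defined.any():
        return
    # run boundaries: value change or defined-mask change
    vals = np.where(defined, arr, np.inf)
    change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
    bounds = np.concatenate([[0], change, [arr.size]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if defined[lo]:
            yield int(lo), int(hi), float(arr[lo])


def _temp_sibling(path) -> str:
    directory = os.path.dirname(os.path.abspath(str(path)))
    fd, tmp = tempfile.mkstemp(prefix=".tmp_", dir=directory)
    os.close(fd)
    return tmp
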