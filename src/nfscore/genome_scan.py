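"""Sliding-window application of the classifier: the NF score tracks.

Two resolutions share the same 147-bp classification window:

* **low resolution** — windows advance by a large step (default 50 bp); each
  window's binary call (1 nucleosomal, 0 linker) is written to the central
  ``step`` base pairs of the window.  Flanks covered by no central segment
  stay gaps.
* **high resolution** — the step (default 7 bp) must divide 147 so that every
  interior base pair falls into exactly 147/step = 21 windows; the per-bp
  score is the fraction of its evaluated covering windows called nucleosomal,
  a vote fraction in [0, 1].

Windows containing non-ACGT bases are excluded — their central segment is a
gap in low resolution, and they drop out of both numerator and denominator in
high resolution.  Coordinates are 0-based half-open; windows start on the
step grid at a configurable phase (default 0).

Featurization is done in bulk: the pentamer predictions are computed once per
reference sequence and each window's four 144-length channel series are
assembled by slicing, which is exactly equivalent to running
:func:`nfscore.shape.compute_shape` + :func:`nfscore.spectral.featurize`
window by window (a unit test asserts this).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .shape import PentamerTable, encode_sequence, step_contributions
from .spectral import (DEFAULT_SPAN, DEFAULT_TAPER, FEATURE_NAMES, N_BINS,
                       _raw_power_matrix, _smooth_rows)
from .track import GenomeTrack

logger = logging.getLogger(__name__)

WINDOW = 147


@dataclass
class ScanConfig:
    """Window/step geometry of a scan."""

    window: int = WINDOW
    step: int = 50
    mode: str = "low_res"  # low_res | high_res
    phase: int = 0

    def __post_init__(self):
        if self.window != WINDOW:
            raise ValueError(f"classification window is fixed at {WINDOW} bp")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.mode not in ("low_res", "high_res"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.mode == "high_res" and self.window % self.step:
            raise ValueError(
                f"high-resolution scanning requires the step to be a divisor "
                f"of the window size of {WINDOW} bp; {self.step} is not"
            )
        if not 0 <= self.phase < self.step:
            raise ValueError("phase must lie in [0, step)")


def window_starts(region_length: int, config: ScanConfig) -> np.ndarray:
    """Start coordinates of all complete windows on the step grid."""
    last = region_length - config.window
    if last < config.phase:
        return np.empty(0, dtype=int)
    return np.arange(config.phase, last + 1, config.step)


def window_coverage(position: int, config: ScanConfig, region_length: int) -> int:
    """Number of complete on-grid windows containing a position.

    An interior base pair at window 147 / step 7 sits in 147/7 = 21 windows;
    edge base pairs are covered by fewer.
    """
    if not 0 <= position < region_length:
        raise ValueError("position outside region")
    lo = max(config.phase, position - config.window + 1)
    hi = min(position, region_length - config.window)
    if hi < lo:
        return 0
    # count multiples of step in [lo-phase, hi-phase]
    lo_k = -((lo - config.phase) // -config.step)  # ceil division
    hi_k = (hi - config.phase) // config.step
    return max(0, int(hi_k - lo_k + 1))


# ---- bulk featurization ----------------------------------------------------

def _channel_series(codes: np.ndarray, table: PentamerTable):
    """Genome-wide per-position MGW/ProT and per-step HelT/Roll ingredients."""
    n = codes.size
    pents = np.full(n, -1, dtype=np.int64)
    if n >= 5:
        window = (codes[:-4] * 256 + codes[1:-3] * 64 + codes[2:-2] * 16
                  + codes[3:-1] * 4 + codes[4:])
        valid = ((codes[:-4] >= 0) & (codes[1:-3] >= 0) & (codes[2:-2] >= 0)
                 & (codes[3:-1] >= 0) & (codes[4:] >= 0))
        pents[2:n - 2] = np.where(valid, window, -1)
    ok = pents >= 0
    safe = np.where(ok, pents, 0)
    mgw = np.where(ok, table.mgw[safe], np.nan)
    prot = np.where(ok, table.prot[safe], np.nan)
    h_before, h_after, r_before, r_after = step_contributions(codes, table)
    return mgw, prot, (h_before, h_after), (r_before, r_after)


def _step_feature_windows(before: np.ndarray, after: np.ndarray,
                          starts: np.ndarray) -> np.ndarray:
    """Window-local HelT/Roll position series, standardized to 144 values.

    Within a window at start ``s`` the defined step-feature positions are the
    window-local positions 1..145; featurization drops the central one
    (see :func:`nfscore.spectral.standardize_channel`).  The window-local
    base-pair steps 1..144 are:

    * step 1 — only the "before" prediction of the pentamer at local center 2;
    * steps 2..143 — mean of the two flanking-pentamer predictions, identical
      to the genome-wide step value;
    * step 144 — only the "after" prediction of the pentamer at local center 144.

    Local positions 1 and 145 take their single defined flanking step;
    positions 2..144 average their two flanking steps.
    """
    w = len(starts)
    steps = np.empty((w, 144))
    steps[:, 0] = before[starts + 1]
    mid = np.arange(2, 144)
    steps[:, 1:143] = 0.5 * (after[starts[:, None] + mid]
                             + before[starts[:, None] + mid])
    steps[:, 143] = after[starts + 144]
    pos = np.empty((w, 145))
    pos[:, 0] = steps[:, 0]
    pos[:, 1:144] = 0.5 * (steps[:, :-1] + steps[:, 1:])
    pos[:, 144] = steps[:, 143]
    return np.delete(pos, 72, axis=1)


def featurize_windows(seq: str, starts: np.ndarray, table: PentamerTable,
                      span: int = DEFAULT_SPAN,
                      taper_p: float = DEFAULT_TAPER) -> pd.DataFrame:
    """PSD feature matrix for 147-bp windows of one reference sequence.

    Equivalent to featurizing each window's own shape profile; all windows
    must consist of ACGT bases only (pre-filter with :func:`valid_windows`).
    """
    codes = encode_sequence(seq)
    starts = np.asarray(starts, dtype=int)
    if starts.size == 0:
        return pd.DataFrame(np.empty((0, 4 * N_BINS)), columns=FEATURE_NAMES)
    mgw, prot, helt_parts, roll_parts = _channel_series(codes, table)

    offs_point = np.arange(2, 145)  # 143 defined single-position values
    blocks = []
    for series in (mgw, prot):
        mat143 = series[starts[:, None] + offs_point]
        # replicate the central value (index 71) to reach the even length 144
        mat = np.concatenate([mat143[:, :72], mat143[:, 71:72], mat143[:, 72:]],
                             axis=1)
        blocks.append(mat)
    blocks.append(_step_feature_windows(*helt_parts, starts))
    blocks.append(_step_feature_windows(*roll_parts, starts))

    feats = np.empty((starts.size, 4 * N_BINS))
    for i, mat in enumerate(blocks):
        if np.isnan(mat).any():
            raise ValueError("window overlaps non-ACGT or table-missing bases")
        power = _raw_power_matrix(mat, taper_p)[:, 1:]
        feats[:, i * N_BINS:(i + 1) * N_BINS] = _smooth_rows(power, span)[:, :N_BINS]
    return pd.DataFrame(feats, columns=FEATURE_NAMES)


def valid_windows(seq: str, starts: np.ndarray) -> np.ndarray:
    """Boolean mask of windows free of non-ACGT bases."""
    codes = encode_sequence(seq)
    bad = (codes < 0).astype(np.int32)
    if bad.any():
        cum = np.concatenate([[0], np.cumsum(bad)])
        return cum[starts + WINDOW] - cum[starts] == 0
    return np.ones(len(starts), dtype=bool)


def _classify(model, features: pd.DataFrame, starts: np.ndarray,
              chrom: str) -> np.ndarray:
    """Route windows through the model; stubs may use starts/chrom."""
    return np.asarray(model.predict_windows(features, starts=starts, chrom=chrom),
                      dtype=int)


def _iter_fasta(genome):
    """Yield (name, sequence) from a pyfaidx Fasta, a path, or a dict."""
    if isinstance(genome, dict):
        yield from genome.items()
        return
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), rebuild=True)
        for name in fa.keys():
            yield name, str(fa[name][:])
        return
    for rec in genome:  # pyfaidx Fasta object
        yield rec.name, str(rec[:])


_CHUNK = 4096  # windows featurized per batch, bounds peak memory


def _scan_windows(seq: str, chrom: str, model, table: PentamerTable,
                  config: ScanConfig, span: int, taper_p: float):
    """Labels for every valid window: (starts, valid mask, labels for valid)."""
    starts = window_starts(len(seq), config)
    if starts.size == 0:
        logger.warning("reference %s shorter than %d bp: no complete window",
                       chrom, config.window)
        return starts, np.zeros(0, dtype=bool), np.zeros(0, dtype=int)
    valid = valid_windows(seq, starts)
    labels = np.zeros(int(valid.sum()), dtype=int)
    vstarts = starts[valid]
    for lo in range(0, vstarts.size, _CHUNK):
        sub = vstarts[lo:lo + _CHUNK]
        feats = featurize_windows(seq, sub, table, span=span, taper_p=taper_p)
        labels[lo:lo + sub.size] = _classify(model, feats, sub, chrom)
    return starts, valid, labels


def scan_low_res(genome, model, table: PentamerTable, step: int = 50,
                 phase: int = 0, span: int = DEFAULT_SPAN,
                 taper_p: float = DEFAULT_TAPER) -> GenomeTrack:
    """Binary NF score: each window's call painted onto its central step bp.

    For step 50 the central segment spans window offsets 48..97 (the 147-50
    leftover splits 48/49, left-biased).  Values are {0,1}; everything not
    covered by a central segment — flanks, masked windows — is a gap.
    """
    config = ScanConfig(step=step, mode="low_res", phase=phase)
    central = (WINDOW - step) // 2
    data = {}
    any_seq = False
    for chrom, seq in _iter_fasta(genome):
        any_seq = True
        arr = np.full(len(seq), np.nan)
        starts, valid, labels = _scan_windows(seq, chrom, model, table,
                                              config, span, taper_p)
        for s, label in zip(starts[valid], labels):
            arr[s + central:s + central + step] = label
        data[chrom] = arr
    if not any_seq:
        raise ValueError("empty genome: no reference sequences")
    return GenomeTrack(data=data, semantics="low_res")


def scan_high_res(region, model, table: PentamerTable, step: int = 7,
                  phase: int = 0, span: int = DEFAULT_SPAN,
                  taper_p: float = DEFAULT_TAPER,
                  drop_partial_edges: bool = False) -> GenomeTrack:
    """Vote-fraction NF score from overlapping windows.

    Per bp: (# covering windows called nucleosomal) / (# covering windows
    evaluated).  Interior base pairs are covered by exactly window/step
    windows; edge base pairs keep their true, smaller coverage as denominator
    unless ``drop_partial_edges`` gaps them instead.  Masked windows leave
    both counts.
    """
    config = ScanConfig(step=step, mode="high_res", phase=phase)
    full_cov = WINDOW // step
    data = {}
    any_seq = False
    for chrom, seq in _iter_fasta(region):
        any_seq = True
        n = len(seq)
        num = np.zeros(n)
        den = np.zeros(n)
        starts, valid, labels = _scan_windows(seq, chrom, model, table,
                                              config, span, taper_p)
        for s, label in zip(starts[valid], labels):
            num[s:s + WINDOW] += label
            den[s:s + WINDOW] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            arr = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        if drop_partial_edges:
            arr[den < full_cov] = np.nan
        data[chrom] = arr
    if not any_seq:
        raise ValueError("empty region set: no reference sequences")
    return GenomeTrack(data=data, semantics="high_res")
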