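"""Synthetic fixtures: labeled sequence sets, toy genomes, toy shape tables,
and peak panels.

The training-set generator emulates the structure of the nucleosome benchmark
used to build the classifier: balanced classes of 147-bp sequences where the
nucleosomal class carries an ~10-bp periodic AA/TT dinucleotide bias — the
rotational signal that lets DNA bend around the histone octamer — and the
linker class carries a stiff poly(dA:dT) tract, the classic nucleosome-
excluding element.  The periodicity is implemented as a placement *bias*, not
a hard repeat, so that the spectral features rather than exact string
matching carry the class signal.  Background composition is uniform
(0.25 per base) with an optional GC skew for robustness experiments.

Every generator is deterministic under its seed and emits syntactically
valid FASTA/BED/TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .intervals_profiles import Interval, IntervalSet, write_bed
from .shape import RC_CODES, PentamerTable, code_to_pentamer

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-class training set.

    Defaults mirror the benchmark the classifier emulates: 2,273 nucleosomal
    and 2,300 linker sequences of 147 bp, ~10-bp dinucleotide periodicity in
    the positive class and 20-40 bp poly(dA:dT) tracts in the negative class.
    """

    n_pos: int = 2273
    n_neg: int = 2300
    seq_length: int = 147
    period: int = 10
    amplitude: float = 0.8
    polyA_tract: tuple = (20, 40)
    gc_skew: float = 0.0  # shifts background away from uniform; 0 = uniform
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class counts must be >= 0")
        if self.period < 2:
            raise ValueError("period must be >= 2")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must be in [0, 1]")
        lo, hi = self.polyA_tract
        if not 1 <= lo <= hi <= self.seq_length:
            raise ValueError("invalid poly(dA:dT) tract length range")
        if not -0.25 <= self.gc_skew <= 0.25:
            raise ValueError("gc_skew must be in [-0.25, 0.25]")


@dataclass
class TrainingSet:
    ids: list
    sequences: list
    labels: np.ndarray
    spec: SyntheticSpec = field(repr=False, default=None)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.ids, self.sequences):
                fh.write(f">{name}\n{seq}\n")


def _background(rng, n, gc_skew):
    p = np.array([0.25 - gc_skew / 2, 0.25 + gc_skew / 2,
                  0.25 + gc_skew / 2, 0.25 - gc_skew / 2])
    return rng.choice(4, size=n, p=p)


def _positive_sequence(rng, spec: SyntheticSpec) -> str:
    """Background with AA/TT dinucleotides placed on the period grid."""
    codes = _background(rng, spec.seq_length, spec.gc_skew)
    offset = int(rng.integers(spec.period))  # random rotational phase
    for g in range(offset, spec.seq_length - 1, spec.period):
        if rng.random() < spec.amplitude:
            base = 0 if rng.random() < 0.5 else 3  # AA or TT
            codes[g:g + 2] = base
    return "".join(BASES[codes])


def _negative_sequence(rng, spec: SyntheticSpec) -> str:
    """Background with one embedded poly(dA:dT) tract."""
    codes = _background(rng, spec.seq_length, spec.gc_skew)
    lo, hi = spec.polyA_tract
    tract = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(0, spec.seq_length - tract + 1))
    codes[start:start + tract] = 0 if rng.random() < 0.5 else 3
    return "".join(BASES[codes])


def gen_training_set(spec: SyntheticSpec) -> TrainingSet:
    """Balanced labeled 147-bp set: periodic positives, tract-bearing negatives."""
    rng = np.random.default_rng(spec.seed)
    ids, seqs, labels = [], [], []
    for i in range(spec.n_pos):
        ids.append(f"nuc_{i:05d}")
        seqs.append(_positive_sequence(rng, spec))
        labels.append(1)
    for i in range(spec.n_neg):
        ids.append(f"lnk_{i:05d}")
        seqs.append(_negative_sequence(rng, spec))
        labels.append(0)
    return TrainingSet(ids=ids, sequences=seqs,
                       labels=np.array(labels, dtype=int), spec=spec)


def gen_toy_pentamer_table(mode: str = "at_content", seed: int = 0) -> PentamerTable:
    """Complete 1024-entry toy shape tables for testing.

    ``constant`` maps every pentamer to the same value in every field;
    ``at_content`` maps values monotonically to the pentamer's A/T count
    (rc-symmetric by construction since A/T count is strand-invariant);
    ``rc_symmetric_random`` draws random values and then enforces the
    reverse-complement symmetry: equal MGW/ProT for a pentamer and its
    reverse complement, swapped HelT/Roll step pairs.
    """
    mgw = np.empty(1024)
    prot = np.empty(1024)
    helt = np.empty((1024, 2))
    roll = np.empty((1024, 2))
    present = np.ones(1024, dtype=bool)

    if mode == "constant":
        mgw[:] = 5.0
        prot[:] = 5.0
        helt[:] = 5.0
        roll[:] = 5.0
        rc_flag = True
    elif mode == "at_content":
        at = np.zeros(1024)
        for c in range(1024):
            pent = code_to_pentamer(c)
            at[c] = pent.count("A") + pent.count("T")
        mgw[:] = 4.0 + 0.4 * at
        prot[:] = -2.0 - 1.5 * at
        helt[:, 0] = helt[:, 1] = 34.0 + 0.5 * at
        roll[:, 0] = roll[:, 1] = -1.0 + 0.7 * at
        rc_flag = True
    elif mode == "rc_symmetric_random":
        rng = np.random.default_rng(seed)
        mgw[:] = rng.normal(5.0, 0.6, 1024)
        prot[:] = rng.normal(-7.0, 3.0, 1024)
        helt[:] = rng.normal(34.5, 2.0, (1024, 2))
        roll[:] = rng.normal(0.0, 3.0, (1024, 2))
        for c in range(1024):
            rc = int(RC_CODES[c])
            if rc > c:
                mgw[rc] = mgw[c]
                prot[rc] = prot[c]
                helt[rc] = helt[c, ::-1]
                roll[rc] = roll[c, ::-1]
        rc_flag = True
    else:
        raise ValueError(f"unknown table mode {mode!r}")

    return PentamerTable(mgw=mgw, prot=prot, helt=helt, roll=roll,
                         present=present, source=f"synthetic:{mode}",
                         rc_symmetric=rc_flag)


@dataclass
class ToyGenome:
    sequence: str
    islands: IntervalSet
    chrom: str = "chrS"

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            seq = self.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    def to_bed(self, path) -> None:
        write_bed(self.islands, path)


def gen_toy_genome(length: int, n_islands: int, seed: int = 0,
                   island_length: int = 441, period: int = 10,
                   amplitude: float = 0.8, tract_every: int = 300,
                   polyA_tract: tuple = (20, 40),
                   chrom: str = "chrS") -> ToyGenome:
    """A linker-like background with embedded nucleosome-favoring islands.

    The background is uniform sequence salted with poly(dA:dT) tracts every
    ~``tract_every`` bp (linker-like); each island is an ``island_length``
    stretch carrying the periodic AA/TT bias of the positive class.  The
    returned truth intervals record the island coordinates for scanner
    validation.
    """
    if length < 147:
        raise ValueError("genome length must be >= 147")
    rng = np.random.default_rng(seed)
    codes = _background(rng, length, 0.0)

    lo, hi = polyA_tract
    pos = int(rng.integers(tract_every // 2, tract_every))
    while pos + hi < length:
        tract = int(rng.integers(lo, hi + 1))
        codes[pos:pos + tract] = 0 if rng.random() < 0.5 else 3
        pos += int(rng.integers(tract_every // 2, tract_every * 3 // 2))

    if n_islands * island_length > length:
        raise ValueError("islands do not fit in the requested length")
    slot = length // max(n_islands, 1)
    islands = []
    for k in range(n_islands):
        lo_s = k * slot
        hi_s = min((k + 1) * slot, length) - island_length
        if hi_s < lo_s:
            raise ValueError("islands do not fit in the requested length")
        start = int(rng.integers(lo_s, hi_s + 1))
        seg = _background(rng, island_length, 0.0)
        offset = int(rng.integers(period))
        for g in range(offset, island_length - 1, period):
            if rng.random() < amplitude:
                seg[g:g + 2] = 0 if rng.random() < 0.5 else 3
        codes[start:start + island_length] = seg
        islands.append(Interval(chrom, start, start + island_length,
                                strand="+", name=f"island_{k}"))
    return ToyGenome(sequence="".join(BASES[codes]),
                     islands=IntervalSet(islands), chrom=chrom)


def gen_peak_panel(n_files: int, covered_bp: int, n_covering: int,
                   out_dir, seed: int = 0, chrom: str = "chr1",
                   genome_length: int = 100_000,
                   peaks_per_file: int = 5) -> list:
    """Write a panel of BED peak files with controlled overlap at one bp.

    Exactly ``n_covering`` of the ``n_files`` files contain a peak
    overlapping ``covered_bp``; the rest place all their peaks away from it.
    Used to exercise the multi-sample accessibility count.
    """
    if not 0 <= n_covering <= n_files:
        raise ValueError("need 0 <= n_covering <= n_files")
    if not 0 <= covered_bp < genome_length:
        raise ValueError("covered_bp outside genome")
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    covering = set(rng.choice(n_files, size=n_covering, replace=False).tolist())
    for i in range(n_files):
        path = os.path.join(str(out_dir), f"panel_{i:04d}.bed")
        with open(path, "w") as fh:
            if i in covering:
                half = int(rng.integers(50, 200))
                s = max(0, covered_bp - half)
                e = min(genome_length, covered_bp + half + 1)
                fh.write(f"{chrom}\t{s}\t{e}\tpeak_hit\t0\t.\n")
            n_extra = int(rng.integers(1, peaks_per_file + 1))
            placed = 0
            while placed < n_extra:
                s = int(rng.integers(0, genome_length - 300))
                e = s + int(rng.integers(100, 300))
                if s <= covered_bp < e:
                    continue  # background peaks must avoid the probe bp
                fh.write(f"{chrom}\t{s}\t{e}\tpeak_bg{placed}\t0\t.\n")
                placed += 1
        paths.append(path)
    return paths
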