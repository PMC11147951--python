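# Methods

## Model

The NF score rests on a binary classifier over 147-bp windows. Its premise is
that nucleosome-favoring DNA differs from linker DNA in *periodic structure*,
not in any fixed motif: an ~10-bp rotational spacing of flexible A/T
dinucleotides lets the double helix bend around the histone octamer, while
rigid homopolymeric dA:dT tracts resist bending. Both signals are structural,
so sequences are first mapped to four DNA-shape parameters (MGW, ProT, HelT,
Roll) through a pentamer lookup, and the classifier then operates on the
power spectral density (PSD) of those shape series. The PSD step is the load-
bearing modeling choice: a periodic pattern contributes the same spectral
power wherever it sits inside the window, so the features are translation-
tolerant by construction, which a per-position representation is not.

### Shape profiles

A pentamer table assigns each 5-mer one MGW and one ProT value (for the
central base pair) and a pair of HelT and Roll values (for the two base-pair
steps flanking the center). Per-position series are assembled as:

- MGW/ProT at position *i*: the value of the pentamer centered at *i*;
  defined at 1-based positions 3..L−2 (L−4 values).
- HelT/Roll: each base-pair step takes the mean of the predictions of the
  (up to two) pentamers flanking it; position *i* then takes the mean of its
  defined flanking steps. The first and last positions have no defined
  flanking step, so L−2 values remain.

For L = 147 this gives 143 + 143 + 145 + 145 = 576 defined values. Non-ACGT
characters are a hard error at this layer; deciding what to do with ambiguous
bases is the genome scanner's job (it drops the window), which keeps
featurization unambiguous.

A table can declare reverse-complement symmetry: MGW/ProT equal between a
pentamer and its reverse complement, HelT/Roll step pairs swapped. Under
that symmetry a profile of the reverse complement is exactly the positional
reversal of the forward profile, a property the test suite exercises.

### Spectral features

Per channel: subtract the mean, taper the first and last ⌊0.1·n⌋ points with
a half-cosine ramp, compute the periodogram `|DFT|²/n`, smooth with a
modified Daniell kernel of span 10 (half-width 5, half-weight endpoints,
reflection at the spectrum edges), and keep one-sided bins 1..72. Bin 0 is
identically ~0 after demeaning and is dropped; the Nyquist bin is kept. The
`|DFT|²/n` normalization is one fixed monotone choice among several
equivalent ones for classification; it makes the Parseval check in the tests
exact (two-sided power sums to the demeaned series' energy).

**Length standardization.** The four channels contribute 143/143/145/145
defined values, but a uniform even length of 144 per channel is the only
simple scheme that yields exactly 576 two-sided coefficients and 288
retained features. MGW/ProT series are brought to 144 by replicating their
*central* value; HelT/Roll by deleting their *central* value. The center —
rather than an end — is adjusted deliberately: a center edit commutes with
positional reversal, so the PSD of a sequence and of its reverse complement
agree to machine precision under an rc-symmetric table. An end edit would
break that symmetry at the ~0.1 level (the padded end maps to the opposite
end under reversal). The distortion of replicating/dropping one interior
point is negligible for smooth shape series and identical across all
sequences, so it cannot carry class signal.

Features are named `MGW_1 … Roll_72`, channel-major, frequency ascending;
index k ≈ k cycles per 147 bp. Whether a different even padding (e.g. to a
composite FFT length) would change downstream results is untested; the
uniform-144 choice is pinned and recorded in the feature names' semantics.

### Classifier

A random forest with explicitly pinned "classic defaults": 500 trees,
⌊√288⌋ = 16 candidate features per split, unlimited depth, no class
weighting; all recorded in the model metadata so deviations are visible. The
prediction probability is the fraction of trees voting nucleosomal (not the
mean of leaf class frequencies), matching the vote-fraction semantics of the
high-resolution score; a tie at 0.5 is classified nucleosomal — an arbitrary
but deterministic and documented rule.

Cross-validation uses stratified folds (classes are near-balanced; stratification
stabilizes per-fold metrics), seeded fold assignment, and reports accuracy,
sensitivity, specificity, F1, AUC and MCC as fold mean ± SD plus the pooled
confusion table. AUC is the rank-based probability that a positive outranks
a negative with ties at ½; MCC substitutes 0 when a denominator factor is 0.

### Genome scoring

Coordinates are 0-based half-open; windows start at phase 0 on the step grid
(the phase is configurable — nothing pins the grid to an absolute genomic
phase, so reproducibility experiments can shift it). Low resolution: step 50,
each window's binary call painted onto window offsets 48..97 (the 147−50=97
leftover splits 48/49, left-biased; a fixed documented constant). High
resolution: the step must divide 147, default 7, score = nucleosomal votes /
evaluated covering windows per bp. Edge base pairs keep their true (smaller)
coverage as denominator, preserving the score's meaning as a vote fraction;
a flag gaps them instead. Windows containing any non-ACGT base are excluded
from numerator and denominator alike — no imputation.

The scanner featurizes windows in bulk by computing pentamer predictions
once per reference and slicing; this is algebraically identical to running
the per-sequence pipeline window by window (asserted by a test), with window-
edge corrections for the HelT/Roll step averaging applied explicitly.

### Intervals, profiles, DHS score

BED3/BED6/narrowPeak-10 inputs; narrowPeak summit offsets are added to
`start`, with the −1 sentinel falling back to the midpoint only when
explicitly enabled. Anchors: point source, midpoint (floor convention,
left-biased for even lengths — the convention is declared, not inferred from
any upstream source), 5′ end, and exon junction (the 5′ boundary in
transcript orientation). Profiles are oriented 5′→3′ (minus-strand extractions
reversed), average over defined values only, and report per-offset support
counts; unstranded intervals are treated as plus with a logged count.
Length-quantile stratification ranks by length, splits into q near-equal
groups (remainder to the shortest groups, ties by input order).

The DHS score counts, per base pair, how many files of a peak panel contain
at least one overlapping peak, deduplicating within each file first. It is a
breadth-of-accessibility measure: with a 403-file panel, 403 means open in
every cell line, 5 in exactly five.

## Synthetic data: what it emulates and what it does not

`gen_training_set` emulates the *structure* of the in vivo benchmark the
classifier targets: balanced classes (defaults 2,273 nucleosomal / 2,300
linker, 147 bp), an AA/TT placement probability of 0.8 on a 10-bp grid with
a random phase per sequence for positives, and a single 20–40-bp poly(dA:dT)
tract at a random position for negatives, over a uniform background
(configurable GC skew). Periodicity is a placement bias, not a hard repeat,
so the spectral features — not exact string matches — carry the signal.

What it does not emulate: MNase digestion bias, genomic base composition and
repeats, the partial overlap between real nucleosomal and linker sequence
statistics, or any in vivo occupancy dynamics. Consequently the synthetic
classes are far more separable than the real benchmark (CV accuracy ~0.97
here vs ~0.82 reported on in vivo data), and passing tests demonstrate that
the pipeline recovers a planted signal faithfully — not that it would reach
any particular accuracy on real chromatin. Likewise the toy pentamer tables
(constant, A/T-content-monotone, rc-symmetric random) are synthetic stand-ins
for a published shape table: they preserve the interfaces and symmetries the
algorithms rely on, not experimentally calibrated shape values.

## Problem sizes and numerical choices

Test fixtures use 500+500 training sequences with 200 trees (chosen so the
binomial SD of a chance-level pooled accuracy is ~0.016, making the ±0.05
permutation-null band a ~3σ bound) and a 150-kb toy genome with 10,000
anchors for the resolution comparison — the anchor count at which the
low-resolution binary track and the high-resolution vote track are compared
in the motivating analysis. The acceptance script scales the classifier back
up to the benchmark-sized 2,273+2,300 set with 500 trees.

Degenerate inputs are errors, not silent defaults: single-class training
sets, non-dividing high-resolution steps, empty genomes, intervals with
`start ≥ end`, incomplete tables under strict loading. Determinism: every
stochastic component takes an explicit seed (generators, training, fold
assignment); identical inputs and seeds reproduce outputs bit-identically.

## Known limitations

- Shape values come from a lookup table; the package ships no experimentally
  derived table and makes no claim about absolute shape accuracy.
- Electrostatic potential is not among the channels; the four-channel
  (MGW/ProT/HelT/Roll) design is what produces the 576/288 feature
  arithmetic, and adding channels would change the feature space.
- The low-resolution score's central-segment convention and the sliding-
  window phase are conventions, not identifiable from data; both are
  documented constants (the phase configurable).
- `dhs_score` holds per-chromosome count arrays in memory; for
  genome-scale panels a streaming implementation would be preferable.
- The forest is a fixed-architecture classifier; no hyperparameter search is
  performed, by design (the pinned defaults are part of the method).
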