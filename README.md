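# nfscore

Sequence-intrinsic nucleosome support from DNA shape.

A nucleosome wraps 147 bp of DNA around a histone octamer, and part of where
nucleosomes sit is written in the DNA itself: an ~10-bp rotational
periodicity of A/T dinucleotides favors wrapping, while stiff poly(dA:dT)
tracts resist it. `nfscore` quantifies this *sequence-intrinsic* nucleosome
support — independent of any particular cell type's in vivo occupancy — as
the **nucleosome formation (NF) score**, for people studying nucleosome
positioning, promoter architecture, and the competition between nucleosomes
and transcription factors.

## The method

1. **DNA shape.** Each 147-bp window is translated, via a pentamer lookup
   table, into four structural profiles: minor groove width (MGW), propeller
   twist (ProT), helix twist (HelT) and roll. Edge positions without a full
   pentamer context are undefined, leaving 4 × 147 − 12 = 576 values.
2. **Power spectra.** Each profile is demeaned, tapered with a split cosine
   bell (p = 0.1), and turned into a periodogram smoothed by a modified
   Daniell kernel (span 10). The 576 two-sided coefficients reduce to
   **288 one-sided features** `MGW_1 … Roll_72`, where `HelT_5` is the HelT
   power at ~5 cycles per 147 bp. Working in frequency space makes the
   features insensitive to where the periodic pattern sits in the window.
3. **Classification.** A random forest (500 trees, 16 features per split)
   labels each window *nucleosomal* (1) or *linker* (0). The model reports
   the six standard metrics under stratified 10-fold cross-validation and
   per-feature Gini importance.
4. **Genome scoring.** The classifier slides across a genome at two
   resolutions: **low** — step 50 bp, each window's binary call painted onto
   its central 50 bp; **high** — step 7 bp (the step must divide 147), so
   every interior bp lies in 147/7 = 21 windows and its score is the fraction
   of those windows called nucleosomal (e.g. 14 of 21 → 14/21 = 0.67).
5. **Interpretation tools.** Strand-aware mean profiles of any track around
   interval anchors (summits, 5′ ends, midpoints, exon junctions),
   length-quantile stratification, and the **DHS score** — a per-bp count of
   how many peak files (e.g. 403 DNase-seq cell-line panels) cover that
   position.

A synthetic-data module generates labeled training sets, toy genomes with
nucleosome-favoring islands, complete toy pentamer tables and peak panels, so
the whole pipeline is testable without any external downloads.

## Worked example

```python
import numpy as np
from nfscore import (SyntheticSpec, gen_training_set, gen_toy_pentamer_table,
                     compute_shape, featurize, cross_validate, train, predict)
from nfscore.spectral import featurize_sequences
from nfscore.classifier import labeled_set_from_features

table = gen_toy_pentamer_table("at_content")          # complete 1024-entry table
spec = SyntheticSpec(n_pos=500, n_neg=500, seed=11)   # periodic vs poly(dA:dT)
ts = gen_training_set(spec)
feats = featurize_sequences(ts.sequences, table, ids=ts.ids)
data = labeled_set_from_features(feats, ts.labels)

report = cross_validate(data, k=10, seed=1, n_trees=200)
for m in ("accuracy", "sensitivity", "specificity", "f1", "auc", "mcc"):
    print(f"{m:12s} {report.mean[m]:.3f} (+/-{report.sd[m]:.3f})")

model = train(data, n_trees=200, seed=1)
out = predict(model, featurize(compute_shape(ts.sequences[0], table)))
print("label", out["label"], "prob", round(out["prob"], 3))
```

prints

```
accuracy     0.967 (+/-0.015)
sensitivity  0.964 (+/-0.023)
specificity  0.970 (+/-0.025)
f1           0.967 (+/-0.015)
auc          0.993 (+/-0.005)
mcc          0.935 (+/-0.030)
label 1 prob 1.0
```

i.e. on synthetic data with a clear class margin the forest separates
nucleosomal from linker windows almost perfectly (accuracy is the fold mean,
the parenthesized value its SD across folds), and the first nucleosomal-class
sequence is called nucleosomal by 100% of trees.

The same pipeline from the shell:

```sh
nf simulate table --mode at_content --out table.tsv
nf simulate training --n-pos 500 --n-neg 500 --seed 11 \
    --out-fasta train.fa --out-labels train.labels.tsv
nf train --fasta train.fa --labels train.labels.tsv --table table.tsv \
    --n-trees 200 --seed 1 --out model.joblib
nf simulate genome --length 50000 --n-islands 10 --seed 2 \
    --out-fasta genome.fa --out-bed truth.bed
nf score --mode high --fasta genome.fa --model model.joblib \
    --table table.tsv --out nf_high.bedgraph
nf profile --track nf_high.bedgraph --intervals truth.bed \
    --mode midpoint --flank 500 --out islands.profile.tsv
```

## Layout

- `nfscore.shape` — pentamer table I/O and shape-profile computation
- `nfscore.spectral` — taper, smoothed periodogram, 288-feature vector
- `nfscore.classifier` — training, metrics, CV, Gini importance
- `nfscore.genome_scan` — low/high-resolution sliding-window scoring
- `nfscore.track` — per-bp tracks, bedGraph/bigWig I/O
- `nfscore.intervals_profiles` — BED/narrowPeak, anchors, mean profiles,
  quantile bins, DHS score
- `nfscore.synthetic` — fixture generators
- `nfscore.cli` — the `nf` command

See `docs/methods.md` for modeling assumptions, parameter choices and known
limitations.
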