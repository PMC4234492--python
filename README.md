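# colonyarray

Quantification and scoring of arrayed microbial colony plates from
Synthetic Genetic Array (SGA) and other plate-based high-throughput
screens.

In an SGA experiment a query mutant is crossed to an arrayed deletion
collection, producing plates of 96–6144 pinned colonies whose sizes
report double-mutant fitness. `colonyarray` takes the flatbed-scanner
images of those plates and turns them into genetic-interaction calls:

1. **scan** — split composite scans (up to four plates per image) into
   oriented greyscale single-plate images, tracking set/plate identity
   through a systematic file-naming scheme.
2. **measure** — binarize each plate at a histogram-derived grey level
   (iterative intermeans, with automatic retry at decreasing levels),
   locate the colony grid (corner-seeded lattice fit with a 30%
   support tolerance, 5% mean-deviation acceptance and ±3° rotation
   retries in 0.5° steps), and assign particles to grid positions
   (quarter-cell centre rule, size limits, circularity ≥ 0.8, with a
   low-stringency rescan that recovers smeared colonies). The output
   is one tab-delimited raw area table per plate.
3. **score** — normalize each plate (divide by the plate median, so an
   average colony scores ~1) with optional row/column, spatial LOESS
   and competition corrections, then pair control and experimental
   replicate sets position by position and attach gene identities from
   an array key file.
4. **analyze** — per position, compute the ratio score
   *r* = exp/ctrl and the difference score *d* = exp − ctrl across
   replicates with a paired two-tailed t-test; filter linked and
   manually excluded genes and slow-growing controls; clamp sizes;
   estimate the low/high ratio cut-offs (*p*, *q*) by extrapolating
   the linear central portion of the sorted-ratio curve; and call a
   hit when the ratio is outside [*p*, *q*], does so in at least
   *n* replicates, and the t-test p-value is below the threshold.
5. **validate** — estimate screen sensitivity TP/(TP+FN) and precision
   TP/(TP+FP) by calibrating against a reference hit set of known
   precision and sensitivity.

A synthetic-fixture module renders ground-truthed plate images (known
pixel areas, planted edge boosts, gradients, smears, rotations) and
simulates paired screens with planted interactions, so the whole
pipeline is testable without scanner data.

## Worked example

Simulate a three-replicate screen, score and analyze it:

```sh
colonyarray simulate --kind screen --seed 7 --out screen
colonyarray score --raw-dir screen --control ctrl --experiment expt \
    --key screen/array.key --out scored
colonyarray analyze --scored scored --export out.tsv
```

prints

```
cutoffs: p=0.911 q=1.085
hits: 1 aggravating, 3 alleviating
```

i.e. the estimated cut-off band is [0.911, 1.085] — per-replicate
ratios inside it are treated as no interaction — and with the default
three-out-of-three replicate requirement and p < 0.05, this null
simulation calls 4 of 1536 positions (0.3%), the expected residual
noise rate. Each row of `out.tsv` carries the position, ORF, control
and experimental means ± SD, ratio, diff, replicate counts outside the
band, p-value and hit status.

Calibrating a screen that found 169 hits, 32 of them shared with a
reference set of 124 hits of precision 0.63 and sensitivity 0.35:

```sh
colonyarray validate --ref-hits 124 --ref-precision 0.63 \
    --ref-sensitivity 0.35 --our-hits 169 --shared 32
```

reports for the calibrated screen TP = 91, FP = 78, FN = 132 out of an
estimated 223 true interactions, hence sensitivity 0.41 and precision
0.54.

The same steps are available as library calls (`colonyarray.scoring`,
`colonyarray.interaction_analysis`, `colonyarray.screen_validation`);
image measurement is `colonyarray.colony_quant.measure_plate`.

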