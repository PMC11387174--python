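# Methods

## Problem and model

`m7gsub` frames regulator–substrate assignment as binary classification of
guanosine-centred sequence windows. For a regulator (METTL1, WDR4, QKI5,
QKI6 or QKI7), a positive site is a guanine inside the regulator's binding
footprint; a negative is any other guanine on the same transcript. The
classifier sees only the window sequence, so the model's assumption is that
substrate specificity is (at least partly) encoded in local sequence
context — consistent with the distinct flanking motifs these regulators
show (e.g. `GxAG`-like context for METTL1).

## Coordinates and sequence handling

All public positions are 1-based and inclusive. Sequences are RNA over
`{A,C,G,U,N}`; `T` is mapped to `U` on ingest and any other character is
rejected. Windows have odd length L with the site G at the centre
((L+1)/2); sites closer than (L−1)/2 to a transcript end are kept and
padded with `N` rather than discarded. Every encoder zero-fills `N`
positions, and composition encoders (NAC, PKC) drop N-containing tuples
from both numerator and denominator, so padding contributes no signal.

## Encoders

* **OH** — 4 bits per position, channel order A,C,G,U (alphabetical; fixed
  once for the whole package).
* **NAC** — overlapping dinucleotide frequencies, denominator L−1
  (overlap is the field convention for short windows); a probability
  vector for N-free input.
* **ANF** — cumulative count of the base at position i within the prefix,
  divided by i; captures positional composition drift.
* **PKC** — Type-I pseudo k-tuple composition. The variant had to be fixed
  here: we use k = 2, λ = 2, w = 0.1 with the EIIP values as the single
  physicochemical property behind the correlation factors
  θ_j = mean_i (EIIP(s_i) − EIIP(s_{i+j}))². This keeps the encoder
  self-contained on constants already used elsewhere in the package; all
  three parameters are configurable, and λ = 0 with k = 2 reduces exactly
  to NAC (tested). The output is Type-I normalized (sums to 1).
* **CP** — chemical-property triples (ring count, functional group,
  hydrogen-bond strength): A=(1,1,1), C=(0,1,0), G=(1,0,0), U=(0,0,1).
* **EIIP** — A=0.1260, U=0.1335, C=0.1340, G=0.0806 per position.

Combined vectors always concatenate in the canonical order OH, NAC, ANF,
PKC, CP, EIIP regardless of request order, and carry a named block layout
that prediction validates against, so a model can never silently consume a
differently encoded matrix.

## Dataset construction

Negatives are sampled per transcript, uniformly without replacement from
non-positive guanines, n = number of positives on that transcript (1:1 by
design; a shortfall is logged, not fatal). The "unmethylated or
unregulated" distinction among negatives is collapsed to "not positive for
this regulator".

Redundancy removal is a greedy incremental clusterer on the fixed-length
windows: scanning in input order (positives first), a window is kept iff
its ungapped identity (matching positions / L) to every kept window is
below the threshold, default 0.9 — the cd-hit-est default. For equal-length
short windows, ungapped identity closely approximates alignment-based
identity, which is why an internal clusterer is used instead of shelling
out to an external binary. Dedupe runs after windowing and jointly over
both classes; both pre- and post-dedupe counts are recorded in the
manifest. Sampling happens before dedupe, so the 1:1 ratio can shrink
slightly if near-duplicates are removed.

The stratified split assigns round(0.8·n_c) of each class to training
(banker's rounding, clamped so neither partition is empty). Every split
carries a manifest (regulator, L, seed, threshold, counts, content hash);
reruns under the same seed are byte-identical.

## Classifiers and metrics

AUROC is computed from average ranks (Mann–Whitney U / (n₊·n₋)), ties
counted ½; it agrees exactly with O(n²) pair counting (tested on random
tied inputs) and is invariant under monotone transforms of the scores.

The SVM uses an RBF kernel. For user-facing scores the fitted SVC is
wrapped in Platt-scaling calibration (`CalibratedClassifierCV`,
`ensemble=False`), which is monotone in the decision value, so rankings and
AUROC match the raw SVM while satisfying the probability contract. During
grid search only raw decision values are ranked — faster and
ranking-equivalent.

The grid spans log₂C ∈ {−3,−1,…,9} and log₂γ ∈ {−15,−13,…,−3}: the
conventional exponent step of 2 over the standard libsvm ranges, 7×7 = 49
cells (the step is configurable). Cells are scored by stratified 5-fold
cross-validation on the training partition; tuning on the held-out test
set would leak, so that protocol is available only behind an explicit
`--tune-on-test` flag for comparison. Ties break toward smaller C, then
smaller γ — the less complex model.

GLM is unpenalized logistic regression; under complete separation it falls
back to a negligible ridge penalty (1e−6) with a warning. RF and gradient
boosting use library defaults with a fixed seed. The classification
threshold behind ACC/Sn/Sp defaults to 0.5 and is exposed everywhere.

## Selection loops

The feature search trains one model per non-empty encoder subset (63) and
scores each on the independent test partition — the protocol the reference
comparison tables use; rank ties prefer fewer encoders. The window sweep
rebuilds the dataset at each length under the same seed so the site sets
stay aligned and only L varies. Cross-prediction applies each regulator's
model to every regulator's held-out test windows; its diagonal reuses the
exact evaluation path, so diagonal cells equal each model's own test AUROC
bit-for-bit. The positive-rate matrix is computed on positive test windows
only (score ≥ threshold).

## Synthetic benchmarks

The generator emulates the structure of real substrate data: i.i.d.
background transcripts (default uniform composition), positive G-sites
whose flank carries a regulator-style motif at a configurable offset
(`x` positions draw from the background, matching degenerate motif
positions), and a `noise_rate` fraction of positives planted without the
motif — mimicking binding regions with no detectable sequence preference.
Negatives may contain the motif by chance, as real background does. Sites
are spaced so planted motifs never overlap. Defaults are 500 positive
sites across 50 transcripts of 2 kb, motif `GxAG` at offset 0, noise 0.1.

What the generator does **not** emulate: splice structure, expression
levels, transcript-specific composition, PWM-weighted (probabilistic)
motifs, or clustered binding sites. Passing tests therefore demonstrate
that the pipeline recovers local sequence signal correctly and
reproducibly — not that real CLIP/RIP-derived substrate sets reach any
particular AUROC; real-data performance depends on external accessions
outside this package's scope.

Test and acceptance problem sizes (80–500 positives, 1.2–2 kb transcripts)
were chosen as the smallest scales at which the planted-signal and null
experiments are statistically stable; the package itself has no size
limits.

## Known limitations

* Ungapped identity slightly under-merges relative to alignment-based
  clustering when near-duplicates are frame-shifted.
* The PKC variant is one member of the PseKNC family; other property sets
  or Type-II weighting are not implemented.
* Negatives are drawn per transcript only; `build_dataset(...,
  exclude_sites=...)` can additionally bar guanines positive for *other*
  regulators from negative sampling, but cross-regulator peak resolution
  is assumed done upstream.
* No class-imbalance handling beyond the 1:1 design, and no deep-learning
  architectures.
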