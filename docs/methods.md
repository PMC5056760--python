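# Methods

## Candidate definition and coordinates

A candidate m⁶A site is an adenosine whose 5-nt context matches DRACH
(D ∈ {A,G,T}, R ∈ {A,G}, A, C, H ∈ {A,C,T}, DNA alphabet). Coordinates
are 0-based; intervals are half-open; the site position indexes the
methylated A, consistent with BED output. Input sequences are accepted
in DNA or RNA spelling and any case; U maps to T, IUPAC ambiguity codes
and other letters map to N, and a candidate is only emitted when its
full pentamer lies inside the sequence and contains no N. Candidates
within 2 nt of a transcript end are therefore excluded symmetrically
for both classes.

The mode tag (`mature` for spliced mRNA, `full` for pre-mRNA/genomic
sequence) selects the feature set and model; it does not change
sequence handling.

## Features

* **Positional one-hot.** Each window base contributes 4 bits in the
  order (G, C, T, A), i.e. A → 0001 … G → 1000; N → 0000. Window
  lengths are 11 nt (mature) and 31 nt (full); both are configurable
  for ablation but the defaults are fixed. Out-of-range positions are
  N-filled, so window length is invariant at transcript ends.
* **k-mer spectrum.** Frequencies of all 3-mers and 4-mers over the
  101-nt window centred on the site (site ± 50 nt, N-padded at
  termini). k-mers containing N are skipped and excluded from the
  normalizing denominator, so each k-block sums to 1 whenever at least
  one clean k-mer exists. Order is lexicographic (A < C < G < T)
  within k, k = 3 before k = 4.
* **Relative position.** pos / (len − 1), so both transcript ends are
  attainable in [0, 1]. Computed only in mature mode.
* **Structure Z-score.** The 101-nt window is folded; its MFE is
  compared with the MFEs of 100 mononucleotide shuffles of the same
  window: z = (MFE − mean) / sd with the sample (n − 1) sd. sd = 0
  (e.g. homopolymer windows) returns z = 0. More stable than its
  shuffles ⇒ z < 0. A dinucleotide-preserving shuffle is not the
  default; the shuffle type and sd convention are recorded in model
  metadata. The per-site shuffle RNG is seeded from a stable hash of
  (base seed, transcript id, position), making each feature vector a
  pure function of (sequence, position, mode, seed), independent of
  batch composition or ordering.

Mature mode concatenates [positional(11), kmer3, kmer4, relpos,
struct_z] → 366 dimensions; full mode [positional(31), kmer3, kmer4]
→ 444. The block layout is stored in the model file.

## Folding model

The built-in folder is a deterministic Nussinov-style dynamic program
over pseudoknot-free structures: weighted base pairs GC = −3, AT = −2,
GU(T) = −1 arbitrary energy units, hairpin loops of at least 3 unpaired
bases, N pairs with nothing. It equals a brute-force enumeration over
all structures on short sequences (tested to 14 nt). It is not a
thermodynamic nearest-neighbour model — absolute energies are not
kcal/mol — but the Z-score only compares a window against shuffles of
itself under the same backend, for which pair-counting stability is the
relevant signal. An adapter (`CommandLineFolder`) plugs in an external
folder (e.g. `RNAfold --noPS`), parsing the trailing parenthesized
energy; the backend name is recorded in the model file, and a window
and its shuffles always use the same backend. The inner loop is
numba-compiled (~0.25 ms per 101-nt fold), which keeps the
100-shuffle Z-score at ~25 ms per site.

## Dataset protocol

Positives are methylated DRACH adenosines given as (transcript id,
position) records; duplicates collapse by identity. Negatives are
sampled uniformly without replacement from DRACH adenosines that are
neither positives nor inside caller-supplied exclusion intervals
(e.g. known methylation peaks; overlap means the adenosine lies within
[start, end)). The split is 75 % train / 25 % test (round() for the
train size), training is balanced 1:1, and the independent test set
holds 10 negatives per positive, matching the scarcity of methylation
among DRACH sites. Train and test are disjoint at the site level, and
test negatives are additionally required to lie ≥ 101 nt from every
training site so that no 101-nt feature window of the test set shares
sequence with a training window — on a real transcriptome such
collisions are negligible, but at simulation scale they otherwise leak
training content into the evaluation (measured as a ±0.04 AUROC bias
on zero-signal data). All sampling derives from one integer seed.
Per-taxon datasets (human, mouse) concatenate into pooled "mammal"
datasets with provenance retained; taxon is metadata, not a code path.

## Classifier

Features are standardized per column with training-set mean/sd;
zero-variance columns pass through unchanged. The SVM uses the RBF
kernel (scikit-learn SVC, libsvm underneath); (C, γ) are chosen by
grid search maximizing mean cross-validated AUROC with ties broken
toward smaller C then smaller γ (default grids C = 2⁻⁵ … 2¹⁵, γ =
2⁻¹⁵ … 2³, factor-4 steps). The ranking score is the signed decision
value, not a Platt probability — decision values suffice for ROC and
threshold logic and avoid an extra calibration fit. The final fit uses
a tight optimizer stopping tolerance (1e-6) so the decision function is
stable (~1e-7) under permutation of training-row order; the grid
search keeps libsvm's default tolerance since it only compares
candidates against each other.

Stringency thresholds: for each target specificity the threshold is
the smallest decision value whose empirical specificity on the
calibration negatives (the training negatives by default; a held-out
split may be supplied instead) reaches the target. Targets are mature
90.0 / 85.2 / 80.0 % and full 93.0 / 88.0 / 83.0 % for high / moderate
/ low. Predictions are monotone in stringency by construction. Models
persist as a joblib archive holding a JSON-able metadata block (format
version, mode, taxon, layout, thresholds, seeds, backend) plus the
numeric state; loading verifies format and version, and round-trips
reproduce scores bit-identically.

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), MCC with the usual
product denominator; zero denominators return 0. AUROC is the rank
statistic with half-credit ties (equal to the trapezoidal ROC area);
AUPR is non-interpolated average precision. FPR ≡ 1 − specificity at
every threshold. Cross-validation is stratified with k = 5 by default
(k is an argument; 7 is sometimes preferred), refits the scaler and
grid search inside each training fold, and pools out-of-fold scores
into a single ROC/PR — pooling is stabler than averaging per-fold
areas at these sample sizes.

## Peak assignment

MeRIP-seq peaks give intervals, optionally with a summit. A 200-nt
window is centred on the summit (interval midpoint when absent) and
truncated at sequence ends. Peaks without a DRACH candidate in the
window are removed first; remaining candidates are scored with a
mature-mode model (a warning is raised otherwise) and the summary
reports the fraction of peaks with ≥ 1 and ≥ 2 predicted sites at the
chosen level (moderate by default). Because only the peak window is
available, relative position and structure features use the window's
own coordinates; the summary flags this (`position_context`).

## Synthetic data

The generator emulates what the features detect. Background
transcripts are i.i.d. with uniform base composition, lengths uniform
in 1200–2000 nt (typical mRNA scale), 200 transcripts and 300 planted
sites by default. Positives are planted by writing an 11-nt context
sampled from a per-position categorical profile (PWM) whose centre is
always DRACH; `signal_strength` s interpolates between background
composition (s = 0) and the sharp consensus TGTGG **GGACT** …
(s = 1; presets: strong 0.8, weak 0.3). Placement is 3′-biased
(relative position ~ Beta(4, 1.5), mean ≈ 0.73) when enabled, and a
15-nt complementary stem is written around half the positives so their
windows fold more stably than shuffles. Planted sites keep ≥ 50 nt
spacing and a 25-nt edge margin — small enough that planted sites see
transcript edges (N-padded windows) about as often as background sites
do. Exclusion intervals of ± 100 nt around planted sites screen the
negative pool, the analogue of screening negatives against known
methylation peaks. The manifest records every generative parameter and
regenerates a bundle bit-identically.

What the generator does **not** emulate: real motif grammar beyond an
11-nt PWM, isoform structure, UTR/CDS architecture, expression-weighted
sampling, or miCLIP error processes. Passing the end-to-end benchmarks
therefore shows the pipeline recovers the kinds of signal it encodes —
positional preference, composition, 3′ bias, structural stability —
not that it attains any particular accuracy on biological data.

## Benchmarks computed by the test suite

* strong-signal bundle (200 transcripts, 300 sites, s = 0.8, seed
  fixed), mature mode, small grid search: held-out AUROC ≈ 0.99
  (threshold: > 0.85);
* zero-signal control (700 transcripts / 1200 sites for statistical
  power), full mode: held-out AUROC within 0.45–0.55;
* AUROC ordered across s ∈ {0, 0.3, 0.8} at fixed seed.

Problem sizes were chosen so the whole suite runs in minutes on one
CPU while keeping the null band ≈ 3 standard errors wide.

## Known limitations

The built-in energy model is a pair-weight heuristic, not a
thermodynamic ensemble; Z-scores from different backends are not
comparable. Threshold calibration on training negatives is slightly
optimistic relative to a held-out calibration split. The peak module's
window-local relative position is not the transcript-level quantity
the mature model was trained on. Grid-search defaults are large;
desk-scale runs should pass reduced grids or fixed hyperparameters.
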