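# Methods

This note documents the models and procedures implemented in `premirscan`,
the study conditions its synthetic generator defines, the numerical choices
made where the design was open, and what the synthetic benchmark does and does
not demonstrate about real data.

## k-mer parameterization

A nucleotide sequence is represented by the frequency vector of its
overlapping k-mers (default k = 4, vocabulary `AAAA…TTTT` in lexicographic
order, 256 features). Windows containing any non-ACGT symbol are discarded and
counts are divided by the number of retained windows, so vectors are
comparable across sequence lengths and rows sum to 1 for unambiguous input; a
fully ambiguous sequence maps to the zero vector. Input is case-insensitive.
No strand collapsing is applied: a sequence and its reverse complement give
vectors related by the k-mer reverse-complement permutation, a property the
test suite uses as an oracle. Counts are not used raw because the inputs span
70–300 nt and longer: frequencies make the representation length-invariant.

## Classifier bench

Five classifiers — SVM with RBF kernel and Platt-calibrated probabilities,
random forest, Gaussian naive Bayes, gradient-boosted trees (XGBoost), and
k-nearest neighbours — are trained on a stratified 70/30 split with library
default hyperparameters and a recorded seed. Performance is reported as
confusion counts at probability threshold 0.5 plus precision, accuracy,
recall, and F-measure exactly as defined by the four standard confusion-matrix
formulas; a zero denominator yields NaN with a warning rather than a silent
zero, so undefined metrics can never inflate an average. ROC curves sweep all
distinct predicted probabilities and AUC uses the trapezoidal rule. Model
selection maximizes F-measure, breaking ties by accuracy and then by the fixed
order SVM, RF, XGBoost, KNN, NB.

## Genome scan

Contigs are scanned with a 70-nt window. Open parameters were fixed as
follows: step 7 nt (10% of the window; step 1 is available for exhaustive
scans), call threshold 0.95 (confirmed-locus probabilities in this kind of
survey are typically ≥ 0.995; the threshold is exposed in `ScanConfig`), both
strands scanned with reverse-strand coordinates mapped back to the forward
strand, and merging of hits that overlap or abut (`merge_gap` = 0). Windows
with no unambiguous k-mer are skipped; windows with some ambiguous k-mers are
classified from the remaining ones. Merged loci carry the maximum window
probability and the number of supporting windows, which is conserved across
merging.

The model used for scanning is an SVM trained on random 70-nt crops of the
training sequences. Training on full-length sequences (70–300 nt) and
deploying on 70-nt windows mixes two different feature distributions — window
vectors are sparser and, over a long hairpin, cover only an arm fragment — and
in that mismatched setting fewer than half of genuinely planted loci receive a
confident window despite high test-set recall. Window-matched training is the
standard remedy and restores stable recovery; the bench itself still trains
and evaluates on full-length sequences.

## Homology search

Candidates are confirmed by an internal seed-and-extend nucleotide search:
exact-match 7-mer seeding over an index of the reference set, ungapped
extension in both directions with an X-drop of 20, +1/−2 match/mismatch
scores, one best alignment per query–subject pair. References are indexed on
the forward strand; queries are searched on both strands. Significance uses
the Karlin–Altschul expectation `E = K·m′·n′·exp(−λS)` with the standard
length adjustment `ℓ = ln(K·m·n)/H`, `m′ = max(m−ℓ, 1)`,
`n′ = max(n−N·ℓ, 1)`. For the +1/−2 ungapped scheme at uniform base
composition the tabulated parameters are λ = 1.33, K = 0.621, H = 1.12
(λ solves Σ pᵢqⱼe^{λsᵢⱼ} = 1); alternative schemes or explicit overrides go
through `HomologyConfig`. Matches at E ≤ 1e−10 are reported sorted by
ascending E. The engine is deliberately self-contained so the stage is
testable without external binaries; it is not a substitute benchmark for any
particular aligner's E-values, which depend on engine and database size.

## SSR mining

A microsatellite locus is a maximal perfect tandem run of a primitive motif
(one that is not itself a repetition of a shorter motif), trimmed to whole
repeats, qualifying when a mononucleotide run is ≥ 10 bases or a 2–6 nt motif
repeats ≥ 5 times. Runs break at ambiguous bases. When qualifying runs
overlap, the longer run wins, ties prefer the shorter motif, then the leftmost
start, so every position belongs to at most one locus; a mononucleotide run is
therefore never double-reported as a dinucleotide repeat. Motifs are reported
as found plus a canonical class label (lexicographically smallest rotation of
the motif or its reverse complement) for grouping. Summaries give counts and
percentages per motif length (two decimals) and density as assembly kb per
locus (one decimal). Only perfect repeats are mined; compound or imperfect
SSRs are out of scope.

## Assembly statistics

N50 follows the cumulative-sum convention on descending lengths, inclusive at
an exact half — the reported value is always the length of a retained contig.
GC% uses only unambiguous bases in the denominator, so GC% + AT% = 100
exactly. The minimum-length filter treats its threshold as inclusive (≥ 500 bp
by default) with a strict mode available.

## Composition and coverage arithmetic

Abundance tables of (class, family, count) rows yield per-family frequencies
within the grand total and within each class (two decimals), class shares and
family-group shares (one decimal), and identified/total coverage percentages
(one decimal). Rounding is decimal half-up on the exact rational value, the
convention of printed report tables. Rows labelled "Ambiguous" belong to no
class: they count toward the grand total only. The package bundles the
published count tables of the quince draft assembly (GenBank JADOBS000000000)
as regression fixtures for this arithmetic; producing such annotations
(domain-based TE classification, TF catalogue searches) is upstream and out of
scope.

## Synthetic study conditions

The generator defines the benchmark conditions; all are in `SimulationConfig`
and driven by one integer seed (stages derive child streams by fixed offsets,
so reruns are byte-identical).

* **Positives** (default 1,000): hairpins `stem + loop + revcomp(stem)`,
  70–300 nt total, loop 4–10 nt, with 5% per-base substitutions on the 3′ arm.
  Sequences are drawn as diverged members (8% per-base divergence) of 100
  archetype families, emulating the strong family redundancy of curated
  pre-miRNA collections, in which conserved families contribute many
  near-identical hairpins across species. Base composition is AU-rich
  (GC 0.36): hairpin loci are non-coding sequence, and in an AT-rich genome
  whose 38.7% average includes the GC-richer coding fraction, non-coding
  composition sits below the average.
* **Negatives** (default 1,000): concatenations of codons drawn uniformly from
  the 61 sense codons (GC ≈ 0.52), length-matched to the positives and free of
  in-frame stops. A custom codon-usage table can be supplied.
* **Genomes**: i.i.d. background at GC 0.387 across 5 contigs of 20–60 kb by
  default (10 × ~100 kb for the 1-Mb scan benchmark), with SSRs and
  full-length family-member hairpins planted at recorded, non-overlapping
  coordinates; bases flanking a planted SSR are forced to break the repeat
  period so truth intervals are exactly the maximal runs. Truth tables are
  written as 0-based half-open BED.

What passing on these conditions shows — and does not. The classes are
separable by construction: family redundancy plus the composition gap carry
the 4-mer signal, mirroring how real hairpin-vs-coding training sets separate,
and all five classifiers reach ≥ 0.9 accuracy under them. It does not show
that the pipeline attains any particular accuracy on real genomes: i.i.d.
synthetic sequence lacks conserved secondary structure, real codon-usage
bias, isochore structure and repeat content. One consequence is deliberate and
visible: i.i.d. background at GC 0.387 lies compositionally closer to the
hairpin class than to coding, so the scanner over-calls on synthetic
background. The false-locus rate on a hairpin-free genome is therefore
reported as a tracked regression quantity (about 7,400 loci/Mb under the
default threshold), and the homology-confirmation stage is what prunes
candidates to family loci — the same scan-then-confirm funnel the real
analysis relies on. The pipeline's `confirm_top_n` (default 500) bounds the
homology stage to the highest-probability candidates.

## Problem sizes and determinism

The shipped benchmarks use 1,000 + 1,000 training sequences, a 1-Mb genome
with 50 planted hairpins for scan recovery, 100 random 10-kb sequences for
SSR oracle parity, and 1,000 random length lists for the N50 oracle — sizes at
which every stage's behaviour is measurable with comfortable statistical
margins on a single CPU. All randomness flows from explicit seeds; identical
configuration and seed reproduce identical outputs, and pipeline manifests
checksum every artifact with the volatile timestamp header excluded.
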