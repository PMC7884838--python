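# premirscan

Machine-learned pre-miRNA locus scanning and repeat/composition
characterization for draft plant genome assemblies — the computational side of
a draft-genome survey, built as a tested, reusable pipeline that runs entirely
on seeded synthetic data.

## What it does

Draft assemblies of under-studied crops (the motivating case is quince,
*Cydonia oblonga*, a ~490 Mb Rosaceae assembly at 38.7% GC) are typically
characterized by a standard battery of analyses. This package implements that
battery:

* **Ab initio pre-miRNA discovery.** Sequences are parameterized as k-mer
  frequency vectors (k = 4, 256 features over lexicographic `AAAA…TTTT`;
  windows containing ambiguous bases are dropped and counts are normalized by
  retained windows). Five classifiers — SVM (RBF), random forest, Gaussian
  naive Bayes, gradient-boosted trees (XGBoost) and k-nearest neighbours — are
  trained on a positive set of hairpin (stem–loop) sequences and a negative
  set of protein-coding fragments with a stratified 70/30 split, and compared
  by

      precision = TP/(TP+FP)        accuracy = (TP+TN)/(TP+TN+FN+FP)
      recall    = TP/(TP+FN)        F        = 2·precision·recall/(precision+recall)

  plus ROC/AUC, selecting the best model (F-measure, ties by accuracy). The
  assembly is then scanned with a 70-nt sliding window (step 7 nt, both
  strands, call threshold 0.95) by an SVM trained on window-sized crops of the
  same training sets, and overlapping window hits merge into candidate
  pre-miRNA loci.
* **Homology confirmation.** Candidate loci are confirmed against a reference
  hairpin set by a self-contained seed-and-extend nucleotide search (exact
  7-mer seeding, ungapped X-drop extension, +1/−2 scoring) with Karlin–Altschul
  significance `E = K·m′·n′·e^(−λS)` at a 1e−10 threshold.
* **Microsatellite (SSR) mining.** Maximal perfect tandem repeats of primitive
  1–6 nt motifs: mononucleotide runs ≥ 10 bases, 2–6 nt motifs ≥ 5 repeats,
  with per-motif-length summaries and overall density in kb per locus.
* **Assembly statistics and composition reports.** N50, GC/AT content,
  length filtering (≥ 500 bp); class/family frequency tables for transposable
  element annotations; coverage percentages for transcription-factor
  catalogues.
* **Synthetic data.** A seeded generator produces family-structured hairpin
  training sets, codon-structured coding negatives, and multi-contig genomes
  with planted SSRs and hairpin loci recorded in a BED truth table, so every
  stage is testable end to end without downloads.

## Worked example

```bash
premirscan run-all --seed 1 --out-dir run1
```

runs simulate → stats → featurize → bench → scan → confirm → ssr → report and
prints the manifest. On the default conditions (1,000 hairpins vs 1,000 coding
fragments, five contigs totalling ≈ 200 kb) the bench metrics table
(`run1/bench_metrics.tsv`) reads:

```
algorithm  tp   fp  tn   fn  precision  accuracy  recall    f_measure
SVM        290  11  289  10  0.963455   0.965000  0.966667  0.965058
RF         292  10  290  8   0.966887   0.970000  0.973333  0.970100
XGBoost    293  11  289  7   0.963816   0.970000  0.976667  0.970199
KNN        297  18  282  3   0.942857   0.965000  0.990000  0.965854
NB         275  11  289  25  0.961538   0.940000  0.916667  0.938567
```

i.e. every classifier separates hairpins from coding fragments at ≥ 0.94
accuracy. The manifest for this run reports the selected model (XGBoost by
F-measure, 0.9702), 1,370 candidate loci from the scan of the ≈ 200 kb
synthetic genome, 136 homology-confirmed matches, 10 mined SSR loci, and
recovery of all 10 planted hairpin loci. Rerunning with the same seed
reproduces byte-identical artifact checksums.

Library use mirrors scikit-learn:

```python
from premirscan import SimulationConfig, make_hairpin_set, make_coding_set
from premirscan import featurize_dataset, split_dataset, train_classifier, evaluate

cfg = SimulationConfig(seed=1)
fm = featurize_dataset(make_hairpin_set(cfg), make_coding_set(cfg))
train, test = split_dataset(fm, 0.7, seed=1)
print(evaluate(train_classifier(train, "SVM", seed=1), test).accuracy)  # 0.965
```

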