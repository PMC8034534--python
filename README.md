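# soluprot

Sequence-based prediction of soluble protein expression in *Escherichia
coli*. Poor solubility is the most common failure mode of protein
production pipelines, and experimental screens are expensive; a predictor
that scores a candidate's probability of soluble (over)expression from its
sequence alone lets protein scientists and enzyme miners prioritize targets
before touching the bench. "Insoluble" here pools targets that never
expressed with targets expressed as inclusion bodies — the practical notion
used in expression labs, not thermodynamic solubility.

## The method

The predictor is a gradient-boosting machine (GBM) over 251 engineered
sequence features in eight groups: single amino-acid content (20), unordered
dimer content (210), physicochemical descriptors (12, incl. pI, GRAVY,
instability index, net charge), average flexibility (1), secondary-structure
content (3), disorder (1) — these three via a plugin interface — predicted
transmembrane-helix content (3), and maximum global identity to a soluble
reference set (1). Features are standardized with training-set statistics;
selection removes one of each pair with Pearson |r| > 0.75 (keeping the
higher GBM importance) and then screens with LASSO, choosing the penalty α
to maximize mean 5-fold cross-validated AUC of a default GBM on the
surviving features. Hyperparameters are tuned by an iterative staged grid
search over the same folds. Prediction scores are probabilities in [0, 1];
a score ≥ 0.5 is classified soluble.

Around the model the package implements the full data pipeline: FASTA I/O
with validity rules (length ≥ 20, standard 20-letter alphabet); global
Needleman–Wunsch identity (BLOSUM62, gap open 10 / extend 1) with greedy
identity clustering for redundancy reduction; curation of noisy
experiment-tracking records into labeled datasets (status-history labeling,
*E. coli* host filtering, transmembrane removal, structural-reference
rescue of mislabeled insolubles, class- and length-balancing, train/test
independence at 25% identity); benchmarking (confusion matrix, ACC, MCC,
ROC/AUC, prioritization enrichment, dataset-overlap analysis); and a
synthetic generator that plants a tunable solubility signal so the whole
pipeline is testable without external downloads. See `docs/methods.md` for
the science and every default.

## Worked example

Train and evaluate on simulated data with a planted signal (positive-charge
content helps solubility, a hydrophobic transmembrane segment hurts):

```bash
soluprot simulate --n 400 --seed 7 --out seqs.fa --labels labels.tsv
soluprot features --fasta seqs.fa --out features.tsv
soluprot train --features features.tsv --labels labels.tsv \
    --out model.sol --seed 7 --alpha-grid 0.02,0.005 --folds 5
# [soluprot] train: 247 features after correlation pruning, 63 selected (alpha=0.02)

soluprot simulate --n 400 --seed 8 --out test.fa --labels test_labels.tsv
soluprot predict --fasta test.fa --model model.sol --out test_pred.tsv
soluprot evaluate --scores test_pred.tsv --labels test_labels.tsv --out report.json
# [soluprot] evaluate: n=400 ACC=0.777 MCC=0.555 AUC=0.855
```

`report.json` then contains:

```json
{
  "AUC": 0.8553, "T": 0.5, "ACC": 0.7775, "MCC": 0.5551,
  "TP": 152, "TN": 159, "FP": 42, "FN": 47
}
```

Read: on 400 held-out sequences the model ranks a random soluble sequence
above a random insoluble one 85.5% of the time (AUC), classifies 77.8%
correctly at the 0.5 threshold, and the Matthews correlation of 0.56
summarizes the balanced confusion matrix. `test_pred.tsv` is a two-column
TSV (`id`, `soluprot_score` in [0, 1], six decimals). Every command also
writes a `.manifest.json` recording its resolved configuration, and the
same functionality is available as a library (`soluprot.fit_pipeline`,
`soluprot.evaluate`, ...).

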