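# Methods

## Problem and model

`soluprot` predicts the probability that a protein is (over)expressed in
soluble form in *E. coli* from its amino-acid sequence alone. "Soluble" here
is the practical, extended notion used in expression pipelines: the
insoluble class pools targets that never expressed with targets that
expressed as inclusion bodies. The predictor is a gradient-boosting machine
(GBM; scikit-learn's `GradientBoostingClassifier`) over engineered sequence
features, preceded by a two-stage feature-selection step and wrapped by the
dataset-curation and benchmarking machinery needed to build and evaluate
such a model end to end.

## Feature vector (251 features, eight groups)

1. **Single amino-acid content** (20): residue counts / length, alphabetical
   order.
2. **Dimer content** (210): overlapping dimers with XY pooled into the
   unordered pair {X,Y} (20·21/2 = 210 features), counts / (length − 1).
3. **Physicochemical descriptors** (12): length; molecular weight; isoelectric
   point; GRAVY (mean Kyte–Doolittle hydropathy); aromaticity; aliphatic
   index 100·(f_A + 2.9 f_V + 3.9 (f_I + f_L)); Guruprasad instability index;
   fraction K+R; fraction D+E; net charge at pH 7; |charge|/residue; fraction
   of small residues (AGSTC). Each is individually switchable by name.
   MW, GRAVY, aromaticity and instability come from Biopython's ProtParam.
4. **Average flexibility** (1) — plugin slot.
5. **Secondary-structure content** (3) — plugin slot.
6. **Average disorder** (1) — plugin slot.
7. **Transmembrane content** (3): predicted TM residues in the whole
   sequence, TM residues within the first 60, and helix count, all derived
   from a per-residue TM mask.
8. **Maximum identity to a soluble reference set** (1): best global identity
   of the query to any member of a user-supplied reference of proteins known
   to express solubly (e.g. structures solved after *E. coli* expression);
   verbatim matches to held-out sequences can be excluded so the reference
   never leaks evaluation data.

Groups 4–6 require external per-residue predictors. They enter only through
the annotator plugin interface (`annotators.AnnotatorSet`); without a plugin
they are filled with a 0.0 sentinel and flagged `excluded`, and the modeling
layer drops flagged features before any selection, so sentinels can never be
selected silently.

**Isoelectric point** is computed by bisection on the Henderson–Hasselbalch
net-charge function with the EMBOSS pKa table (N-term 8.6, C-term 3.6,
K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1), tolerance 1e-4 pH
units. Net charge is strictly decreasing in pH, so the root is unique; the
same function supplies the two charge features.

**Default TM annotator**: sliding Kyte–Doolittle window of 19 residues,
mean hydropathy ≥ 1.6 marks every residue of the window; overlapping marked
windows merge into one helix. This is a deliberately simple, dependency-free
stand-in behind the same contract a full TM topology predictor would use
(the three features map 1:1 onto a TM predictor's expected-residue,
first-60 and helix-count summaries), and any such predictor can be plugged
in.

**Standardization**: features are centered and scaled to unit variance with
statistics computed on the training set only; zero-variance training columns
get scale 1 (they standardize to exactly 0). Selected-feature subsets are
always sliced by name, never by position.

## Sequence identity

Global identity uses a Needleman–Wunsch alignment (Biopython
`PairwiseAligner`): BLOSUM62, affine gaps with open 10 / extend 1 (a gap of
length L costs 10 + (L−1)), terminal gaps penalized. Identity = identical
aligned pairs / alignment columns — the definition database search tools
report by default. The pair is put in lexicographic order before aligning so
identity is symmetric even when co-optimal alignments differ in identity
count. Exact DP replaces the heuristic engines used at database scale; at
desk scale exactness is preferable and the tests verify agreement with an
exhaustive alignment-enumeration oracle on short sequences.

Redundancy reduction is greedy centroid clustering: sequences sorted by
decreasing length (ties by id) each join the first centroid at identity ≥
threshold (default 0.25) or found a new cluster; the sort makes the output
independent of input order. Clustering runs separately for the soluble and
insoluble classes so that redundancy removal cannot simplify the prediction
problem by collapsing across classes.

## Dataset curation

Labeling from experiment records is asymmetric by design: **soluble**
requires a status history containing a soluble state (default vocabulary:
soluble, purified, crystallized, diffraction, NMR assigned, structure
deposited — explicit config); **insoluble** requires an *explicit* stop
status matching an insolubility keyword (expression failed, insoluble,
purification failed, no expression) *and* no soluble state reached; anything
else is unknown and excluded. The explicit-stop requirement trades recall
for precision on the insoluble class, because unlabeled failures are
dominated by non-solubility causes.

The pipeline then: filters to *E. coli* expression (protocol keyword match
or a confirmed-protocol allow-list); removes transmembrane proteins (direct
annotation or TM-annotator call); enforces sequence validity (length ≥ 20,
20-letter alphabet); "rescues" insoluble-labeled sequences that appear
verbatim in the soluble structural reference (they are removed as
mislabeled — an exact-identity criterion, since no threshold is defensible
without structure metadata); reduces redundancy per class; and balances both
class size and the length distribution by downsampling the over-represented
class uniformly (seeded) within 25-residue length bins, dropping bins
present in only one class. Length balancing exists because length
correlates with solubility but is useless for ranking within a protein
family — the intended use case. A test set is made independent of training
data by dropping every test sequence with > 25% global identity to any
training sequence. Every step logs in/out counts; the attrition report
chains exactly.

## Feature selection and training

1. A default-parameter GBM is fitted on all (standardized, non-sentinel)
   features to obtain impurity importances.
2. **Correlation pruning**: among each feature pair with Pearson |r| > 0.75
   the lesser-importance member is dropped. Pairs are processed in
   descending |r| with lexicographic tie-breaks (and the lexicographically
   later name dropped on equal importance), making the result deterministic;
   survivors provably contain no pair above the cap.
3. **LASSO screening**: for each alpha on a descending grid (library default:
   0.08 → 0, step 6.25e-4; max_iter 10000, tol 1e-4, on standardized
   features) the nonzero-coefficient features form a candidate set; the
   winning alpha maximizes mean 5-fold cross-validated AUC of a
   default-parameter GBM on that set, ties resolved toward the larger alpha
   (fewer features). Candidate sets are deduplicated before CV, and the
   stratified, seeded folds are shared across the whole grid.
4. **Staged hyperparameter tuning** (optional): an ordered list of grids,
   one or two parameters per stage (tree count + learning rate; depth +
   minimum split; minimum leaf; row subsample; feature subsample; tree-count
   refinement at lower learning rate; regularization refinement). Each stage
   keeps earlier winners fixed and untouched parameters at library defaults,
   maximizing the same shared-fold CV AUC; a full audit trail is retained.
5. The final model is trained on the full training matrix with the chosen
   features and parameters; the saved archive (zip of JSON manifest +
   joblib booster) carries the selected feature names, standardizer
   statistics, hyperparameters and seed, so scoring is byte-reproducible.

Scores are the booster's class-1 probability in [0, 1]; classification uses
score ≥ threshold (default 0.5, boundary inclusive by convention).

## Evaluation

Confusion matrix at a threshold; accuracy; Matthews correlation coefficient
with the zero-denominator convention MCC = 0 (needed for degenerate
matrices); ROC by scikit-learn's `roc_curve` with trapezoidal AUC, which the
tests verify equals the all-pairs Mann–Whitney statistic with half-credit
ties. Prioritization enrichment ranks by score, keeps the top ⌈f·n⌉ at each
fraction f and compares observed true positives with the analytic random-
selection expectation f·n·prevalence (non-integer allowed); enrichment =
observed/expected − 1. Dataset-overlap analysis counts exact sequence
matches between two labeled sets and scores the second set's labels against
the first's as a confusion matrix.

## Synthetic data generator

The generator defines the study conditions for end-to-end validation.
`gen_sequences` draws sequences of length 60–300 (uniform) with i.i.d.
residues from a uniform background (a Swiss-Prot-like frequency preset is
available for realism); with probability 0.30 a hydrophobic 21-mer (drawn
from LIVFAM) is spliced in, which the default TM annotator detects. Labels
are Bernoulli draws from a logistic model on batch-z-scored realized
features with per-SD weights {fraction K+R: +1.5, TM-segment presence:
−1.2, isoelectric point: +0.6}, plus N(0, 0.5) noise and an intercept set
by the target prevalence (default 0.5). The weights point the way protein
chemistry suggests — surface charge helps, hydrophobic TM segments hurt —
and their magnitudes were chosen once to give a learnable but non-trivial
signal (Bayes-optimal AUC well below 1). Everything is deterministic per
seed.

What the generator does **not** emulate: homology structure (sequences are
i.i.d., so redundancy reduction and independence filtering are exercised
only structurally), compositional autocorrelation along real sequences,
any real relationship between dimer patterns and solubility, and
label noise correlated with lab protocol. Passing the recovery tests
therefore shows the pipeline can find a planted composition/TM/charge
signal at realistic sample sizes — not that it reproduces real-data
accuracy, which depends on the external training corpora.

`gen_curation_records` emits tracking records from a scenario mixture
(soluble path, insoluble stop, unknown, non-coli host, transmembrane,
PDB-rescuable), with the rescuable sequences also placed in the returned
structural reference; post-curation counts have closed-form expectations.

## Problem sizes and numerical choices

The shipped validation runs use desk-scale sizes chosen as the package's
own defaults: end-to-end recovery at n = 2000 (1600 train / 400 held out,
seed 1) with a coarse LASSO grid {0.02, 0.005, 0.001} — the full 129-point
grid with per-candidate CV is a batch-computing exercise that changes
nothing structurally — and a label-shuffled null at n = 500 over 10 seeds.
Observed under these conditions (also recomputed by
`scripts/acceptance.py`): held-out AUC ≈ 0.84 against the ≥ 0.8 recovery
bar, null mean AUC ≈ 0.51. Identity oracles enumerate all alignments for
lengths ≤ 6 over a 4-letter alphabet. All tolerances of record: pI bisection
1e-4 pH; LASSO tol 1e-4; correlation cap 0.75; identity threshold 0.25;
score threshold 0.5.

## Known limitations

- The physicochemical feature list is a documented default set of 12; other
  reasonable definitions (e.g. different pKa tables) shift pI by ~0.1–0.5
  units. The pKa table is fixed and exposed.
- The default TM annotator is a hydropathy heuristic; it finds planted
  hydrophobic segments reliably but is not a topology predictor. Real use
  should plug in a dedicated tool.
- Greedy length-sorted clustering approximates, not reproduces, the cluster
  assignments of heuristic database tools at the same threshold.
- Trained-model quality on real data depends entirely on the curated corpus
  supplied; the package ships no pretrained weights.
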