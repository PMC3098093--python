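# zftarget

Tools for predicting which 9-bp DNA sites can be successfully targeted by
three-finger C2H2 zinc finger arrays engineered with Oligomerized Pool
ENgineering (OPEN), and for finding candidate zinc finger nuclease (ZFN)
sites in DNA sequences.

## Who this is for

OPEN assembles a three-finger array from pre-built pools of recognition-helix
variants, one pool per 3-bp triplet subsite of a 9-bp target. Running a
selection is laborious, and not every theoretically targetable site yields a
binding array. Given a gene of interest with many candidate sites, an
experimentalist wants to rank them by the probability that OPEN will succeed.
`zftarget` provides that ranking, plus the surrounding bookkeeping: target-
space enumeration, methylation-based exclusion, and scanning of sequences for
ZFN full sites (two inverted 9-bp half-sites around a 5–7 bp spacer).

## The model

A site `s = s1…s9` (5'→3') is classified by a categorical Naïve Bayes model
with Laplace smoothing (pseudocount α, default 1):

    P(c | s) ∝ P(c) · ∏ᵢ P(sᵢ | c),      c ∈ {active, inactive}
    P(c)        = (n_c + α) / (N + 2α)
    P(sᵢ=v | c) = (count(v, c) + α) / (n_c + arity·α)

Three encodings are supported: the sequence identity itself (9 categorical
attributes, arity 4), whole-site base counts (4 attributes over {0..9}), and
positional base counts (12 attributes over {0..3}: each base's count at the
1st/2nd/3rd position within a triplet). A site is called *active* when
P(active | s) ≥ θ (default θ = 0.5), and the posterior is condensed to a
0–9 **confidence score**: one unit per 0.05 of posterior beyond 0.5 on either
side, capped at 9 (so posterior 0.75 → active with confidence 5, posterior
0.25 → inactive with confidence 5).

An RBF-kernel SVM protocol is also provided for comparison: because labeled
site datasets are imbalanced (~4:1 active), each prediction averages
calibrated probabilities over k randomized class-balanced training sets
(default k = 10). Evaluation is by leave-one-out cross-validation with the
standard confusion-matrix measures (accuracy, Matthews correlation,
specificity⁺ = TP/(TP+FP), sensitivity⁺ = TP/(TP+FN)) and a tie-aware
Mann–Whitney ROC AUC.

## Worked example

Simulate a labeled dataset with the realistic thymine-penalized activity
model (79% active), cross-validate the classifier, and summarize the
targetable space:

```sh
zftarget simulate --n 135 --seed 1 --out sites.tsv
zftarget loocv sites.tsv --report-out report.tsv
head -13 report.tsv
```

```
metric	value
accuracy	0.77037
cc	0.20788
specificity_plus	0.808333
sensitivity_plus	0.92381
fpr	0.766667
tpr	0.92381
auc	0.650794
threshold	0.5
TP	97
FP	23
TN	7
FN	8
```

At n = 135 the thymine signal is learnable but noisy: the classifier calls
most truly active sites correctly (sensitivity⁺ 0.92) but, with only 30
inactive examples, its precision for inactives is limited (CC 0.21,
AUC 0.65). Larger simulated datasets push the AUC toward the Bayes ceiling
of the generative model (≈0.73 at the default effect size).

```sh
zftarget enumerate --out -
```

```
quantity	value
n_enumerable	12558
n_methylation_excluded	124
n_targetable	12434
n_predicted_active	
n_zfn_pairs	154604356
n_zfn_pairs_unordered	77308395
```

With triplet pools of sizes 26/21/23 the enumerable space is
26·21·23 = 12,558 distinct 9-mers. Sites containing a dam (GATC) or dcm
(CCAGG/CCTGG) motif are excluded — these are methylated in the E. coli host
of the selection assay, which blocks binding. (The shipped pool lists are
size-accurate placeholders, so the exclusion count differs from that of the
unpublished true pools.) ZFN full sites pair any two targetable half-sites,
counted as ordered pairs (n²).

Scanning a FASTA file for ZFN sites, with per-half-site classification:

```sh
zftarget train sites.tsv --model-out model.json
zftarget scan genome.fa --model model.json --min-confidence 6 --out hits.tsv
```

## Layout

- `src/zftarget/core.py` — domain types; site-table/FASTA/pool-config I/O
- `src/zftarget/encodings.py` — the three site encodings
- `src/zftarget/classifiers.py` — Naïve Bayes (from scratch), confidence
  score, balanced resampling, RBF-SVM protocol, CC-maximizing threshold
- `src/zftarget/evaluation.py` — LOOCV drivers, metrics, ROC/AUC
- `src/zftarget/composition.py` — base-composition analytics
- `src/zftarget/target_space.py` — enumeration, methylation filter, scanning
- `src/zftarget/synthetic.py` — synthetic labeled-site generator
- `src/zftarget/cli.py` — the `zftarget` command

See `docs/methods.md` for the modeling details and design choices.
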