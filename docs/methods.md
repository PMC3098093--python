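# Methods

## Problem setting

A three-finger C2H2 zinc finger array recognizes a 9-bp DNA site, one finger
per 3-bp triplet subsite, read 5'→3' on the bound strand. OPEN (Oligomerized
Pool ENgineering) selects such arrays combinatorially from per-triplet finger
pools; a site is *active* when the selection yields at least one array that
binds it (≥3-fold activation in the bacterial two-hybrid reporter) and
*inactive* otherwise. The package predicts this label from sequence alone,
before any selection is attempted.

## Classifier

The primary classifier is a categorical Naïve Bayes model over one of three
encodings of the site:

| encoding | attributes | value domain (arity) |
|---|---|---|
| sequence identity | 9 | {G,A,C,T} (4) |
| base counts | 4 (G,A,C,T totals) | {0..9} (10) |
| positional base counts | 12 (3 within-triplet positions × 4 bases) | {0..3} (4) |

Count-valued attributes are treated as *nominal* values of bounded arity, not
as Gaussian-distributed numerics. The arities are tiny and the nominal
treatment avoids an arbitrary distributional assumption; a Gaussian variant
was considered and rejected because nothing in the data model motivates a
continuous likelihood for a count in {0..3}.

Smoothing is additive (Laplace) with pseudocount α on both priors and
conditionals:

    P(c)        = (n_c + α)/(N + 2α)
    P(xᵢ=v | c) = (count(v,c) + α)/(n_c + arityᵢ·α)

α defaults to 1, which keeps every probability strictly positive; α = 0 is
allowed on explicit request (zero conditionals then short-circuit a class).
Posteriors are computed in log space and renormalized, so products of 9–12
small probabilities never underflow; a brute-force direct-product oracle
agrees to 1e−10 in property tests.

**Decision rule and confidence.** A site is called active when
P(active | x) ≥ θ; θ defaults to 0.5 and the tie classifies active. The
0–9 confidence score is floor(|p − 0.5| / 0.05), capped at 9, with a 1e−9
epsilon added before the floor so that exact multiples of 0.05 (which are
not exactly representable in binary floating point) land on the intended
step. Optionally θ can be chosen to maximize the Matthews correlation
coefficient over pooled cross-validation posteriors; candidate thresholds
are 0, 1 and midpoints between adjacent distinct posteriors, with ties
broken toward the smallest candidate. This in-sample threshold choice is
optimistic by construction, so the fixed-θ path is the default for held-out
evaluation.

## SVM protocol

Validated site datasets are imbalanced (roughly 4:1 active:inactive), which
biases a margin classifier toward the majority class. The protocol therefore
trains k (default 10) RBF-kernel support-vector classifiers, each on a
balanced set containing *all* minority-class sites plus an equal-size uniform
sample (without replacement) of the majority class, and averages their
calibrated probability estimates. The SVC solver and its Platt-style
probability calibration come from scikit-learn; the balanced resampling,
averaging, leave-one-out embedding, and the CC-driven grid search
(C ∈ 2⁻⁵..2¹⁵, γ ∈ 2⁻¹⁵..2³, factor-4 steps, 5 stratified internal folds,
ties toward smaller C then smaller γ) are this package's code. Identity
encodings are one-hot expanded for the kernel; count encodings are used as
numeric vectors.

## Evaluation

Leave-one-out cross-validation: each site is scored by a model fitted on the
remaining N−1 sites (for the SVM protocol, the balanced sets are drawn from
those N−1, so the test site can never leak into training). The ROC curve is
built from the pooled LOOCV posteriors — the only construction that yields a
single curve from LOOCV — with one operating point per distinct score and
ties grouped into a single jump. AUC is the tie-aware Mann–Whitney
statistic; the trapezoidal area under the curve is the same number and is
kept as an independent oracle in tests (agreement to 1e−12 over fuzzed score
sets). Degenerate 0/0 metric denominators produce NaN, printed as `NA`,
never a silent 0 or 1. Held-out evaluation refuses train/test pairs that
share any sequence, and can stratify its report by confidence score
(≥ s vs < s).

## Target space and ZFN scanning

The targetable 9-mer space is the Cartesian product of the three triplet
pools. Pool identities are not public; the shipped configuration reproduces
the known sizes (26/21/23, product 12,558) with all 16 GNN triplets plus
provisional TNN choices and is explicitly marked as a placeholder. Sites
containing a dam (GATC) or dcm (CCAGG/CCTGG) motif are excluded as
unassayable in the E. coli selection host; the motif set is closed under
reverse complement, so a one-strand substring search covers both strands.
The exclusion is applied within the 9-bp half-site only, keeping pool-space
counts context-free.

A ZFN full site is left(9) + spacer(5–7) + right(9) in forward-strand
coordinates; the two bound half-sites are reverse_complement(left) and
right, both pointing 5'-ends-inward so the FokI domains dimerize over the
spacer. This geometry makes scanning strand-closed — scanning W and its
reverse complement yields the same unordered half-site pairs at mirrored
coordinates — so a single forward-strand pass suffices (verified as a
property test over random sequences). Windows containing N are skipped.
ZFN pair counts use ordered pairs (n²), the convention consistent with
published genome-scale counts; the deduplicated unordered count n(n+1)/2 is
reported alongside. Reports print 1-based first-base coordinates;
internally everything is 0-based half-open.

## Synthetic data

The generator draws sites uniformly (with replacement) from the pool product
and labels them with a logistic activity model:

    P(active | s) = σ(β₀ + βT·countT(s) + Σₚ bonus[p, base(p)])

The thymine coefficient βT (default −1.0) encodes the dominant empirical
signal — thymine content depresses targeting success at every within-triplet
position — and the optional 9×4 positional bonus allows position-specific
effects. When a target active fraction is requested (default 0.79, matching
validated datasets), β₀ is solved by bisection so the *expected* fraction
over the sampled sites equals it; the realized fraction then varies
binomially. All randomness descends from one integer seed through named
generator streams (sampling and labeling are independent streams, so
relabeling does not perturb the sequences).

What the generator does *not* emulate: OPEN selection chemistry, reporter
fold-activation values, correlations between triplet identity and activity
beyond base composition, and expert pre-filtering of candidate sites.
Passing tests on synthetic data therefore demonstrate that the machinery
recovers planted statistical structure, not that real sites obey the
logistic model.

Two calibration facts about the defaults, measured by the test suite: with
βT = 0 the LOOCV AUC at n = 200 is statistically indistinguishable from
chance, and with βT = −1.0 the Bayes-optimal classifier itself reaches only
AUC ≈ 0.72–0.74 on pool-drawn sites (the thymine-count spread in the pool
space is modest), so the learned classifier is asserted to approach that
ceiling rather than an arbitrary absolute level.

## Numerical and I/O choices

- Attribute order is fixed as (G, A, C, T) everywhere.
- Site tables are headered TSV (`sequence`, `label`, `id`) with a tolerant
  CSV reader; labels normalize case-insensitively and any token other than
  active/inactive/unknown is an error, because silent coercion would corrupt
  training.
- Models serialize to a versioned JSON document (schema, α, priors, full
  conditional tables); reloading reproduces posteriors bit-identically
  because JSON round-trips doubles exactly.
- Problem sizes in the default test run (e.g. LOOCV at n ≤ 500, 10-seed
  averages, 100-construction scanning properties) were chosen to make the
  statistical assertions stable at 3σ-style tolerances while keeping the
  suite fast on one core.

## Known limitations

- The shipped pool lists are placeholders; methylation-exclusion and
  predicted-active counts over the real OPEN pools will differ.
- Reproduction of published per-dataset performance requires the original
  validated site tables, which are not redistributable here; the
  corresponding tests fail until the user supplies them under `data/`.
- The smoothing constants and nominal-vs-numeric treatment of count
  encodings in other Naïve Bayes implementations differ; digit-exact
  agreement with externally published tables may require matching those
  conventions (α is exposed for this reason).
- No annotation handling (exon/transcript bookkeeping), no off-target
  scoring, and no FokI heterodimer variant logic.
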