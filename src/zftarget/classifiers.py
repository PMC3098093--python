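"""Classifiers for 9-bp target-site activity.

The primary model is a categorical Naive Bayes classifier written from
scratch: Laplace-smoothed class priors and per-attribute conditional tables
over small discrete domains, with posterior arithmetic in log space.  A
support-vector protocol is layered over scikit-learn's RBF-kernel SVC: the
class imbalance of validated site datasets (~4:1 active:inactive) is
handled by averaging calibrated probabilities across k randomized balanced
training sets.

The posterior is mapped to a 0-9 confidence score: one unit per 0.05 of
posterior beyond the 0.5 decision point, capped at 9, on either side.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from zftarget.core import SiteDataset, TargetSite
from zftarget.encodings import (
    EncodingKind,
    FeatureVector,
    attribute_domains,
    encode_site,
)

CLASSES = ("active", "inactive")

# libsvm practitioners' guide grids: C in 2^-5..2^15, gamma in 2^-15..2^3,
# stepping by factors of 4.
DEFAULT_COST_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision threshold and threshold-selection policy."""

    threshold: float = 0.5
    optimize_cc: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold {self.threshold} outside [0, 1]")


@dataclass(frozen=True)
class PredictionResult:
    site: TargetSite
    posterior_active: float
    label: str
    confidence: int


@dataclass(frozen=True)
class SvmProtocolConfig:
    """RBF-SVM protocol: kernel parameters and balanced-resampling count."""

    cost: float = 1.0
    gamma: float | str = "scale"
    n_balanced_sets: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_balanced_sets < 1:
            raise ValueError("n_balanced_sets must be >= 1")


@dataclass
class NaiveBayesModel:
    """Smoothed categorical Naive Bayes over one site encoding.

    priors[c]         = (n_c + alpha) / (N + 2*alpha)
    conditional[i][c][v] = (count(attr i == v, class c) + alpha)
                           / (n_c + arity_i * alpha)

    With alpha >= 1 every probability is strictly positive.  alpha = 0 is
    permitted on explicit request and may yield zero conditionals.
    """

    kind: EncodingKind
    alpha: float
    priors: dict[str, float]
    # conditionals[attr_index][class][value] = probability
    conditionals: list[dict[str, dict]]
    domains: list[tuple] = field(repr=False, default_factory=list)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "format": "zftarget-nb-model",
            "version": 1,
            "kind": self.kind,
            "alpha": self.alpha,
            "priors": self.priors,
            "conditionals": [
                {c: {str(v): p for v, p in table.items()} for c, table in attr.items()}
                for attr in self.conditionals
            ],
            "domains": [[str(v) for v in dom] for dom in self.domains],
        }
        return json.dumps(doc, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "NaiveBayesModel":
        doc = json.loads(text)
        if doc.get("format") != "zftarget-nb-model":
            raise ValueError("not a zftarget Naive Bayes model document")
        kind = doc["kind"]
        cast = str if kind == "identity" else int
        domains = [tuple(cast(v) for v in dom) for dom in doc["domains"]]
        conditionals = [
            {c: {cast(v): p for v, p in table.items()} for c, table in attr.items()}
            for attr in doc["conditionals"]
        ]
        return cls(
            kind=kind,
            alpha=doc["alpha"],
            priors=doc["priors"],
            conditionals=conditionals,
            domains=domains,
        )

    @classmethod
    def load(cls, path: str | Path) -> "NaiveBayesModel":
        return cls.from_json(Path(path).read_text())


def nb_fit(
    training: Sequence[tuple[FeatureVector, str]], alpha: float = 1.0
) -> NaiveBayesModel:
    """Fit the smoothed Naive Bayes model on encoded (vector, label) pairs."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if not training:
        raise ValueError("empty training set")
    kinds = {vec.kind for vec, _ in training}
    if len(kinds) != 1:
        raise ValueError(f"mixed encodings in training set: {sorted(kinds)}")
    kind = kinds.pop()
    labels = [label for _, label in training]
    for label in labels:
        if label not in CLASSES:
            raise ValueError(f"unlabeled or invalid training label {label!r}")
    n_by_class = {c: labels.count(c) for c in CLASSES}
    missing = [c for c, n in n_by_class.items() if n == 0]
    if missing:
        raise ValueError(f"training set has no {missing[0]!r} instances")

    n_total = len(training)
    priors = {
        c: (n_by_class[c] + alpha) / (n_total + 2 * alpha) for c in CLASSES
    }
    domains = attribute_domains(kind)
    n_attrs = len(domains)
    # one counting pass over the data per class
    counts = {c: [dict.fromkeys(domains[i], 0) for i in range(n_attrs)] for c in CLASSES}
    for vec, label in training:
        tables = counts[label]
        for i, v in enumerate(vec.values):
            tables[i][v] += 1
    conditionals: list[dict[str, dict]] = []
    for i in range(n_attrs):
        arity = len(domains[i])
        attr_tables: dict[str, dict] = {}
        for c in CLASSES:
            denom = n_by_class[c] + arity * alpha
            attr_tables[c] = {
                v: (n + alpha) / denom for v, n in counts[c][i].items()
            }
        conditionals.append(attr_tables)
    return NaiveBayesModel(
        kind=kind, alpha=alpha, priors=priors, conditionals=conditionals,
        domains=domains,
    )


def nb_posterior(model: NaiveBayesModel, x: FeatureVector) -> float:
    """P(active | x) via Bayes' rule, computed in log space and renormalized."""
    if x.kind != model.kind:
        raise ValueError(
            f"feature kind {x.kind!r} does not match model kind {model.kind!r}"
        )
    if len(x.values) != len(model.conditionals):
        raise ValueError("feature vector length does not match model schema")
    log_joint = {}
    for c in CLASSES:
        total = math.log(model.priors[c]) if model.priors[c] > 0 else -math.inf
        for i, v in enumerate(x.values):
            table = model.conditionals[i][c]
            if v not in table:
                raise ValueError(
                    f"value {v!r} of attribute {i} outside model domain"
                )
            p = table[v]
            total += math.log(p) if p > 0 else -math.inf
        log_joint[c] = total
    m = max(log_joint.values())
    if m == -math.inf:
        return 0.5  # both classes impossible under alpha=0; no evidence
    weights = {c: math.exp(log_joint[c] - m) for c in CLASSES}
    return weights["active"] / (weights["active"] + weights["inactive"])


def confidence_score(posterior_active: float) -> int:
    """Map a posterior to the 0-9 confidence scale.

    One unit per 0.05 of posterior beyond 0.5 (above for active calls,
    below for inactive calls), capped at 9.  A tiny epsilon guards exact
    multiples of 0.05 against binary floating-point representation.
    """
    p = posterior_active
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"posterior {p} outside [0, 1]")
    eps = 1e-9
    distance = p - 0.5 if p >= 0.5 else 0.5 - p
    return min(9, int(math.floor(distance / 0.05 + eps)))


def nb_predict(
    model: NaiveBayesModel,
    site: TargetSite,
    config: ClassifierConfig = ClassifierConfig(),
) -> PredictionResult:
    """Classify one site: active iff posterior >= threshold."""
    x = encode_site(site, model.kind)
    p = nb_posterior(model, x)
    label = "active" if p >= config.threshold else "inactive"
    return PredictionResult(
        site=site, posterior_active=p, label=label, confidence=confidence_score(p)
    )


def balanced_subsets(
    dataset: SiteDataset, k: int, seed: int
) -> list[list[TargetSite]]:
    """k class-balanced training sets from an imbalanced labeled dataset.

    Each set contains every minority-class site plus an equal number of
    majority-class sites drawn uniformly without replacement (independently
    per set).  Deterministic given the seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dataset.require_both_classes()
    active = [s for s in dataset.sites if s.label == "active"]
    inactive = [s for s in dataset.sites if s.label == "inactive"]
    minority, majority = (
        (inactive, active) if len(inactive) <= len(active) else (active, inactive)
    )
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(k):
        idx = rng.choice(len(majority), size=len(minority), replace=False)
        sampled = [majority[i] for i in sorted(idx)]
        subsets.append(list(minority) + sampled)
    return subsets


def _to_matrix(vectors: Iterable[FeatureVector]) -> np.ndarray:
    """Numeric design matrix for the SVM (identity bases -> one-hot)."""
    rows = []
    for vec in vectors:
        if vec.kind == "identity":
            row = []
            for v in vec.values:
                row.extend(1.0 if v == b else 0.0 for b in "GACT")
            rows.append(row)
        else:
            rows.append([float(v) for v in vec.values])
    return np.asarray(rows, dtype=float)


def _fit_svc(
    X: np.ndarray, y: np.ndarray, config: SvmProtocolConfig, seed: int
) -> SVC:
    clf = SVC(
        kernel="rbf",
        C=config.cost,
        gamma=config.gamma,
        probability=True,
        random_state=seed,
    )
    clf.fit(X, y)
    return clf


def svm_averaged_posterior(
    test_vector: FeatureVector,
    balanced_sets: Sequence[Sequence[TargetSite]],
    config: SvmProtocolConfig = SvmProtocolConfig(),
) -> float:
    """Mean calibrated P(active) over one RBF-SVM per balanced training set.

    The caller must ensure the test site is absent from every training set
    (the LOOCV driver enforces this).
    """
    kind = test_vector.kind
    X_test = _to_matrix([test_vector])
    probs = []
    for j, subset in enumerate(balanced_sets):
        labels = {s.label for s in subset}
        if labels != {"active", "inactive"}:
            raise ValueError(f"balanced set {j} is single-class: {sorted(labels)}")
        X = _to_matrix(encode_site(s, kind) for s in subset)
        y = np.array([1 if s.label == "active" else 0 for s in subset])
        clf = _fit_svc(X, y, config, seed=config.seed + j)
        p = clf.predict_proba(X_test)[0][list(clf.classes_).index(1)]
        probs.append(p)
    return float(np.mean(probs))


def _cc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = math.sqrt(
        float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    )
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def choose_threshold_max_cc(
    posteriors: Sequence[tuple[float, str]]
) -> float:
    """Threshold maximizing the Matthews correlation coefficient.

    Candidates are 0, 1 and the midpoints between adjacent distinct
    posterior values; ties break toward the smallest threshold.
    """
    labels = {label for _, label in posteriors}
    if labels - {"active", "inactive"}:
        raise ValueError(f"invalid labels: {sorted(labels - set(CLASSES))}")
    if labels != {"active", "inactive"}:
        raise ValueError("both classes required to optimize the threshold")
    distinct = sorted({p for p, _ in posteriors})
    candidates = [0.0]
    candidates += [
        (a + b) / 2.0 for a, b in zip(distinct, distinct[1:])
    ]
    candidates.append(1.0)
    best_theta, best_cc = None, -math.inf
    for theta in candidates:
        tp = sum(1 for p, l in posteriors if p >= theta and l == "active")
        fp = sum(1 for p, l in posteriors if p >= theta and l == "inactive")
        fn = sum(1 for p, l in posteriors if p < theta and l == "active")
        tn = sum(1 for p, l in posteriors if p < theta and l == "inactive")
        cc = _cc_from_counts(tp, fp, tn, fn)
        if cc > best_cc:  # strict: earlier (smaller) candidate wins ties
            best_theta, best_cc = theta, cc
    return float(best_theta)


def grid_search_rbf(
    training: Sequence[tuple[FeatureVector, str]],
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 1,
) -> tuple[float, float]:
    """Pick (cost, gamma) maximizing internal cross-validated CC.

    Stratified k-fold CV on the training set; folds whose test part is
    single-class contribute nothing (degenerate-fold rule).  Ties break
    toward smaller cost, then smaller gamma.
    """
    if not cost_grid or not gamma_grid:
        raise ValueError("parameter grids must be non-empty")
    labels = [label for _, label in training]
    if len(set(labels)) < 2:
        raise ValueError("both classes required for grid search")
    X = _to_matrix(vec for vec, _ in training)
    y = np.array([1 if label == "active" else 0 for label in labels])
    n_splits = min(folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("too few instances of the minority class for CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None  # (cc, cost, gamma)
    for cost in sorted(cost_grid):
        for gamma in sorted(gamma_grid):
            tp = fp = tn = fn = 0
            for train_idx, test_idx in splits:
                if len(set(y[test_idx])) < 2:
                    continue  # degenerate fold: skip
                clf = SVC(kernel="rbf", C=cost, gamma=gamma)
                clf.fit(X[train_idx], y[train_idx])
                pred = clf.predict(X[test_idx])
                truth = y[test_idx]
                tp += int(np.sum((pred == 1) & (truth == 1)))
                fp += int(np.sum((pred == 1) & (truth == 0)))
                tn += int(np.sum((pred == 0) & (truth == 0)))
                fn += int(np.sum((pred == 0) & (truth == 1)))
            cc = _cc_from_counts(tp, fp, tn, fn)
            if best is None or cc > best[0]:
                best = (cc, cost, gamma)
    assert best is not None
    return best[1], best[2]
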