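"""Cross-validation drivers and classification performance measures.

Measures follow the standard confusion-matrix definitions with the
"active" class as positive:

    accuracy      = (TP + TN) / (TP + FP + TN + FN)
    CC            = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))
    specificity+  = TP / (TP + FP)        (precision)
    sensitivity+  = TP / (TP + FN)        (recall)
    FPR           = FP / (FP + TN)
    TPR           = TP / (TP + FN)

Degenerate 0/0 denominators yield NaN (printed "NA"), never a silent 0 or
1.  AUC is the tie-aware Mann-Whitney statistic; the trapezoidal area under
the ROC curve is identical and serves as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from zftarget.classifiers import (
    ClassifierConfig,
    NaiveBayesModel,
    SvmProtocolConfig,
    balanced_subsets,
    choose_threshold_max_cc,
    confidence_score,
    nb_fit,
    nb_posterior,
    svm_averaged_posterior,
)
from zftarget.core import SiteDataset, TargetSite
from zftarget.encodings import EncodingKind, encode_dataset, encode_site

Scored = tuple[float, str]  # (posterior of active, true label)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    counts: ConfusionCounts
    accuracy: float
    cc: float
    specificity_plus: float
    sensitivity_plus: float
    fpr: float
    tpr: float
    roc: list[tuple[float, float]]
    auc: float
    threshold: float
    posteriors: list[Scored] = field(default_factory=list)


def _check_labels(predictions: Sequence[Scored]) -> None:
    bad = {l for _, l in predictions if l not in ("active", "inactive")}
    if bad:
        raise ValueError(f"unknown labels in predictions: {sorted(bad)}")


def confusion(predictions: Sequence[Scored], threshold: float) -> ConfusionCounts:
    """Tally the confusion matrix at a threshold (posterior >= θ → active)."""
    _check_labels(predictions)
    tp = fp = tn = fn = 0
    for p, label in predictions:
        called_active = p >= threshold
        if label == "active":
            if called_active:
                tp += 1
            else:
                fn += 1
        else:
            if called_active:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, denom: float) -> float:
    return num / denom if denom else math.nan


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """The six scalar measures from a confusion matrix (0/0 → NaN)."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    cc_denom = math.sqrt(float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    return {
        "accuracy": _ratio(tp + tn, counts.total),
        "cc": (tp * tn - fp * fn) / cc_denom if cc_denom else math.nan,
        "specificity_plus": _ratio(tp, tp + fp),
        "sensitivity_plus": _ratio(tp, tp + fn),
        "fpr": _ratio(fp, fp + tn),
        "tpr": _ratio(tp, tp + fn),
    }


def _require_both_classes(predictions: Sequence[Scored]) -> None:
    labels = {l for _, l in predictions}
    if labels != {"active", "inactive"}:
        raise ValueError("both classes required")


def roc_curve(predictions: Sequence[Scored]) -> list[tuple[float, float]]:
    """(FPR, TPR) points, one per distinct score threshold, plus anchors.

    Thresholds descend over distinct posterior values; tied scores move the
    operating point in a single jump.
    """
    _check_labels(predictions)
    _require_both_classes(predictions)
    n_pos = sum(1 for _, l in predictions if l == "active")
    n_neg = len(predictions) - n_pos
    points = [(0.0, 0.0)]
    tp = fp = 0
    ordered = sorted(predictions, key=lambda x: -x[0])
    i = 0
    while i < len(ordered):
        score = ordered[i][0]
        while i < len(ordered) and ordered[i][0] == score:
            if ordered[i][1] == "active":
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((fp / n_neg, tp / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def auc(predictions: Sequence[Scored]) -> float:
    """Tie-aware Mann-Whitney AUC.

    (#{active score > inactive score} + 0.5 * #ties) / (n_active * n_inactive).
    """
    _check_labels(predictions)
    _require_both_classes(predictions)
    pos = [p for p, l in predictions if l == "active"]
    neg = [p for p, l in predictions if l == "inactive"]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def trapezoid_auc(predictions: Sequence[Scored]) -> float:
    """Trapezoidal area under :func:`roc_curve` (cross-check oracle)."""
    pts = roc_curve(predictions)
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def _assemble_report(
    predictions: Sequence[Scored], config: ClassifierConfig
) -> EvalReport:
    theta = config.threshold
    if config.optimize_cc:
        theta = choose_threshold_max_cc(list(predictions))
    counts = confusion(predictions, theta)
    m = metrics(counts)
    return EvalReport(
        counts=counts,
        accuracy=m["accuracy"],
        cc=m["cc"],
        specificity_plus=m["specificity_plus"],
        sensitivity_plus=m["sensitivity_plus"],
        fpr=m["fpr"],
        tpr=m["tpr"],
        roc=roc_curve(predictions),
        auc=auc(predictions),
        threshold=theta,
        posteriors=list(predictions),
    )


def _check_cv_dataset(dataset: SiteDataset) -> None:
    if dataset.count("active") < 2 or dataset.count("inactive") < 2:
        raise ValueError(
            "leave-one-out cross-validation needs >= 2 sites per class"
        )


def loocv_nb(
    dataset: SiteDataset,
    kind: EncodingKind,
    alpha: float = 1.0,
    config: ClassifierConfig = ClassifierConfig(),
) -> EvalReport:
    """Leave-one-out CV of the Naive Bayes classifier (deterministic)."""
    _check_cv_dataset(dataset)
    encoded = encode_dataset(dataset, kind)
    predictions: list[Scored] = []
    for i, (x, label) in enumerate(encoded):
        training = encoded[:i] + encoded[i + 1 :]
        model = nb_fit(training, alpha=alpha)
        predictions.append((nb_posterior(model, x), label))
    return _assemble_report(predictions, config)


def loocv_svm_balanced(
    dataset: SiteDataset,
    kind: EncodingKind,
    svm_config: SvmProtocolConfig = SvmProtocolConfig(),
    config: ClassifierConfig = ClassifierConfig(),
) -> EvalReport:
    """Leave-one-out CV of the balanced-resampling SVM protocol.

    Per held-out site: build k balanced training sets from the remaining
    sites, average the calibrated SVM probabilities.  Reproducible given
    the protocol seed.
    """
    _check_cv_dataset(dataset)
    predictions: list[Scored] = []
    for i, site in enumerate(dataset.sites):
        rest = SiteDataset(
            name=f"{dataset.name}-fold{i}",
            sites=dataset.sites[:i] + dataset.sites[i + 1 :],
        )
        subsets = balanced_subsets(
            rest, svm_config.n_balanced_sets, seed=svm_config.seed + i
        )
        x = encode_site(site, kind)
        p = svm_averaged_posterior(x, subsets, svm_config)
        predictions.append((p, site.label))
    return _assemble_report(predictions, config)


def evaluate_holdout(
    model: NaiveBayesModel,
    test: SiteDataset,
    config: ClassifierConfig = ClassifierConfig(),
    confidence_threshold: Optional[int] = None,
) -> tuple[EvalReport, Optional[dict[str, EvalReport]]]:
    """Evaluate a fitted model on an independent labeled test set.

    When ``confidence_threshold`` s is given, also reports metrics
    stratified into the high-confidence (score >= s) and low-confidence
    (score < s) subsets.  AUC in a stratum is NaN if it is single-class.
    """
    predictions: list[Scored] = []
    confidences: list[int] = []
    for site in test.sites:
        p = nb_posterior(model, encode_site(site, model.kind))
        predictions.append((p, site.label))
        confidences.append(confidence_score(p))
    report = _assemble_report(predictions, config)
    strata = None
    if confidence_threshold is not None:
        strata = {}
        for name, keep in (
            (f">={confidence_threshold}", lambda c: c >= confidence_threshold),
            (f"<{confidence_threshold}", lambda c: c < confidence_threshold),
        ):
            sub = [pr for pr, c in zip(predictions, confidences) if keep(c)]
            if not sub:
                continue
            theta = report.threshold
            counts = confusion(sub, theta)
            m = metrics(counts)
            labels = {l for _, l in sub}
            has_both = labels == {"active", "inactive"}
            strata[name] = EvalReport(
                counts=counts,
                accuracy=m["accuracy"],
                cc=m["cc"],
                specificity_plus=m["specificity_plus"],
                sensitivity_plus=m["sensitivity_plus"],
                fpr=m["fpr"],
                tpr=m["tpr"],
                roc=roc_curve(sub) if has_both else [],
                auc=auc(sub) if has_both else math.nan,
                threshold=theta,
                posteriors=sub,
            )
    return report, strata


def check_disjoint(train: SiteDataset, test: SiteDataset) -> None:
    """Raise if any test sequence also occurs in the training set."""
    overlap = {s.sequence for s in train.sites} & {s.sequence for s in test.sites}
    if overlap:
        raise ValueError(
            f"train/test overlap on {len(overlap)} sequence(s), "
            f"e.g. {sorted(overlap)[:3]}"
        )


def train_and_evaluate(
    train: SiteDataset,
    test: SiteDataset,
    kind: EncodingKind,
    alpha: float = 1.0,
    config: ClassifierConfig = ClassifierConfig(),
    confidence_threshold: Optional[int] = None,
) -> tuple[EvalReport, Optional[dict[str, EvalReport]]]:
    """Fit on all of ``train`` and evaluate on a disjoint ``test`` set."""
    check_disjoint(train, test)
    train.require_both_classes()
    model = nb_fit(encode_dataset(train, kind), alpha=alpha)
    return evaluate_holdout(model, test, config, confidence_threshold)


def _fmt(x: float) -> str:
    return "NA" if isinstance(x, float) and math.isnan(x) else f"{x:.6g}"


def write_report(report: EvalReport, path: str | Path) -> None:
    """Metric block + confusion counts + per-site posterior rows as TSV."""
    lines = ["metric\tvalue"]
    for name in (
        "accuracy", "cc", "specificity_plus", "sensitivity_plus", "fpr", "tpr",
        "auc", "threshold",
    ):
        lines.append(f"{name}\t{_fmt(getattr(report, name))}")
    c = report.counts
    lines.append(f"TP\t{c.tp}")
    lines.append(f"FP\t{c.fp}")
    lines.append(f"TN\t{c.tn}")
    lines.append(f"FN\t{c.fn}")
    lines.append("")
    lines.append("posterior\ttrue_label\tpredicted_label\tconfidence")
    for p, label in report.posteriors:
        pred = "active" if p >= report.threshold else "inactive"
        lines.append(f"{p!r}\t{label}\t{pred}\t{confidence_score(p)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_roc(report: EvalReport, path: str | Path) -> None:
    lines = ["fpr\ttpr"]
    lines += [f"{x!r}\t{y!r}" for x, y in report.roc]
    Path(path).write_text("\n".join(lines) + "\n")
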