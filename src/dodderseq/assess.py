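"""Competitive-mapping assessment of read classification quality.

To measure how often reads end up on the wrong species, single-species
read libraries (from tissue never in contact with the other plant) are
mapped against the union of both species' contig sets and each read is
assigned by the better-scoring side. With the read's source species as
ground truth this yields a read-level confusion matrix, per-library
misclassification rates (percent of a library cross-mapped), TPR/FPR and
a single-operating-point ROC AUC:

    TPR = TP / (TP + FN),  FPR = FP / (FP + TN),
    AUC = (1 + TPR - FPR) / 2

i.e. the trapezoidal area through (0,0), (FPR,TPR), (1,1). A continuous
variant (`auc_from_scores`) sweeps a margin score and reduces exactly to
the single-point formula for hard binary assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .align import AlignmentHit
from .classify import AMBIGUOUS, SPECIES_A, SPECIES_B, UNCLASSIFIED


@dataclass(frozen=True)
class ConfusionMatrix:
    """Read-level confusion counts with a designated positive species."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive_label: str = SPECIES_A

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def tpr(self) -> float:
        if self.tp + self.fn == 0:
            raise ValueError("no positives presented: TPR undefined")
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        if self.fp + self.tn == 0:
            raise ValueError("no negatives presented: FPR undefined")
        return self.fp / (self.fp + self.tn)


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.tpr <= 1.0 and 0.0 <= self.fpr <= 1.0):
            raise ValueError("tpr and fpr must lie in [0, 1]")


@dataclass(frozen=True)
class AssessmentReport:
    """The cells a misclassification table is built from: the confusion
    matrix, per-library cross-mapping rates and mapped fractions (percent
    of each library's total reads), and the ROC AUC."""

    confusion: ConfusionMatrix
    misclassification_rate_a: float
    misclassification_rate_b: float
    mapped_fraction_a: float
    mapped_fraction_b: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        cm = self.confusion
        return {
            "tp": cm.tp,
            "fn": cm.fn,
            "fp": cm.fp,
            "tn": cm.tn,
            "tpr": cm.tpr,
            "fpr": cm.fpr,
            "misclassification_rate_a": self.misclassification_rate_a,
            "misclassification_rate_b": self.misclassification_rate_b,
            "mapped_fraction_a": self.mapped_fraction_a,
            "mapped_fraction_b": self.mapped_fraction_b,
            "auc": self.auc,
        }


def _hit_key(hit: AlignmentHit) -> tuple:
    # e-value first (every preset gates on it), then identity, then bitscore
    return (-hit.evalue, hit.identity, hit.bitscore)


def competitive_choice(
    best_hit_a: Optional[AlignmentHit], best_hit_b: Optional[AlignmentHit]
) -> str:
    """Binary choice between the best hit on each side of a merged
    reference: the better (e-value asc, identity desc, bitscore desc)
    side wins; exact ties are ambiguous; no hits at all is unclassified."""
    if best_hit_a is None and best_hit_b is None:
        return UNCLASSIFIED
    if best_hit_b is None:
        return SPECIES_A
    if best_hit_a is None:
        return SPECIES_B
    ka, kb = _hit_key(best_hit_a), _hit_key(best_hit_b)
    if ka > kb:
        return SPECIES_A
    if kb > ka:
        return SPECIES_B
    return AMBIGUOUS


def competitive_margin(
    best_hit_a: Optional[AlignmentHit], best_hit_b: Optional[AlignmentHit]
) -> float:
    """Signed margin backing :func:`competitive_choice`: positive favours
    species A. The magnitude is the bit-score difference (or the winning
    bit score when only one side mapped); zero for ties or no hits."""
    if best_hit_a is None and best_hit_b is None:
        return 0.0
    if best_hit_b is None:
        return best_hit_a.bitscore
    if best_hit_a is None:
        return -best_hit_b.bitscore
    choice = competitive_choice(best_hit_a, best_hit_b)
    if choice == AMBIGUOUS:
        return 0.0
    delta = abs(best_hit_a.bitscore - best_hit_b.bitscore)
    if delta == 0.0:
        delta = np.finfo(float).tiny  # comparator broke the tie on e-value/identity
    return delta if choice == SPECIES_A else -delta


def confusion_from_labels(
    truth: Mapping[str, str],
    predicted: Mapping[str, str],
    positive_label: str = SPECIES_A,
    negative_label: Optional[str] = None,
) -> ConfusionMatrix:
    """Build the confusion matrix from per-read truth and predictions.

    Both mappings must cover the same read ids. Ambiguous/unclassified
    predictions are excluded from the matrix (tally them separately with
    :func:`label_tally` if needed).
    """
    if set(truth) != set(predicted):
        missing = set(truth) ^ set(predicted)
        raise ValueError(f"truth/prediction read ids differ (e.g. {sorted(missing)[:3]})")
    labels = {positive_label} | set(truth.values())
    if negative_label is None:
        others = labels - {positive_label}
        if len(others) != 1:
            raise ValueError(f"cannot infer the negative label from truth labels {sorted(labels)}")
        negative_label = others.pop()
    tp = fn = fp = tn = 0
    for rid, t in truth.items():
        p = predicted[rid]
        if p not in (positive_label, negative_label):
            continue
        if t == positive_label:
            tp += p == positive_label
            fn += p == negative_label
        elif t == negative_label:
            fp += p == positive_label
            tn += p == negative_label
        else:
            raise ValueError(f"read {rid!r}: unknown truth label {t!r}")
    return ConfusionMatrix(tp, fn, fp, tn, positive_label)


def label_tally(predicted: Mapping[str, str]) -> dict[str, int]:
    tally: dict[str, int] = {}
    for label in predicted.values():
        tally[label] = tally.get(label, 0) + 1
    return tally


def misclassification_rate(cross_mapped: int, library_total: int) -> float:
    """Percent of a library's total reads mapped to the wrong species."""
    if library_total < 1:
        raise ValueError("library_total must be >= 1")
    if not (0 <= cross_mapped <= library_total):
        raise ValueError("cross_mapped must lie in [0, library_total]")
    return 100.0 * cross_mapped / library_total


def auc_single_point(cm: ConfusionMatrix) -> float:
    """ROC AUC of a single operating point: (1 + TPR - FPR) / 2."""
    return (1.0 + cm.tpr - cm.fpr) / 2.0


def auc_from_scores(
    truth: Sequence[str],
    scores: Sequence[float],
    positive_label: str = SPECIES_A,
) -> float:
    """Trapezoidal ROC AUC from a sweep over all margin-score thresholds.

    For hard binary scores (e.g. +-1 margins) this equals
    :func:`auc_single_point` exactly: the sweep visits (0,0), (FPR,TPR)
    and (1,1) and the two trapezoids sum to (1+TPR-FPR)/2. The AUC is
    invariant under strictly monotone transforms of the scores.
    """
    y = np.asarray([t == positive_label for t in truth], dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.size == 0 or y.all() or not y.any():
        raise ValueError("need at least one positive and one negative")
    if np.unique(s).size == 1:
        warnings.warn("all scores identical; AUC degenerates to 0.5", stacklevel=2)
        return 0.5
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep only the last point of each tied-score group
    boundary = np.append(s[1:] != s[:-1], True)
    tpr = np.concatenate([[0.0], tps[boundary] / tps[-1]])
    fpr = np.concatenate([[0.0], fps[boundary] / fps[-1]])
    return float(np.trapezoid(tpr, fpr))


def assessment_report(
    truth: Mapping[str, str],
    predicted: Mapping[str, str],
    positive_label: str = SPECIES_A,
    library_total_a: Optional[int] = None,
    library_total_b: Optional[int] = None,
) -> AssessmentReport:
    """Assemble the full assessment: confusion matrix, per-library rates
    relative to the library totals (defaulting to the presented reads of
    each species), and the single-point AUC."""
    cm = confusion_from_labels(truth, predicted, positive_label)
    n_a = sum(t == positive_label for t in truth.values())
    n_b = len(truth) - n_a
    total_a = library_total_a if library_total_a is not None else n_a
    total_b = library_total_b if library_total_b is not None else n_b
    return AssessmentReport(
        confusion=cm,
        misclassification_rate_a=misclassification_rate(cm.fn, total_a),
        misclassification_rate_b=misclassification_rate(cm.fp, total_b),
        mapped_fraction_a=misclassification_rate(cm.tp, total_a),
        mapped_fraction_b=misclassification_rate(cm.tn, total_b),
        auc=auc_single_point(cm),
    )
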