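"""Classification metrics and the leakage-aware population-wise data split.

SWD (*D. suzukii*) is the positive class, DM (*D. melanogaster*) the
negative class. Because one insect can trigger the sensor many times,
near-duplicate records exist within a population; random splits would leak
them across train and test. The population-wise split therefore assigns
whole populations to either the train+validation side or the test side:
per species the largest population trains, all others test, and the
train-side records are split 80/20 into train and validation by seeded
random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIVE = "SWD"
NEGATIVE = "DM"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with SWD = positive, DM = negative."""
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, labels: np.ndarray, predictions: np.ndarray
                         ) -> "ConfusionMatrix":
        y = np.asarray(labels).astype(int)
        p = np.asarray(predictions).astype(int)
        if y.shape != p.shape:
            raise ValueError("labels and predictions must align")
        return cls(tp=int(np.sum((y == 1) & (p == 1))),
                   fp=int(np.sum((y == 0) & (p == 1))),
                   tn=int(np.sum((y == 0) & (p == 0))),
                   fn=int(np.sum((y == 1) & (p == 0))))

    def to_frame(self) -> pd.DataFrame:
        """Rows = true class (DM, SWD), columns = predicted class."""
        return pd.DataFrame([[self.tn, self.fp], [self.fn, self.tp]],
                            index=pd.Index([NEGATIVE, POSITIVE], name="true"),
                            columns=pd.Index([NEGATIVE, POSITIVE], name="predicted"))


def recall(cm: ConfusionMatrix) -> float:
    if cm.tp + cm.fn == 0:
        raise ZeroDivisionError("recall undefined: no positive ground truth")
    return cm.tp / (cm.tp + cm.fn)


def precision(cm: ConfusionMatrix) -> float:
    if cm.tp + cm.fp == 0:
        raise ZeroDivisionError("precision undefined: no positive predictions")
    return cm.tp / (cm.tp + cm.fp)


def f1(cm: ConfusionMatrix) -> float:
    p, r = precision(cm), recall(cm)
    if p + r == 0:
        raise ZeroDivisionError("F1 undefined: precision + recall = 0")
    return 2 * p * r / (p + r)


def balanced_accuracy(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Mean of per-class recall; 1 for perfect, 0 for fully inverted."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("balanced accuracy needs both classes in the labels")
    cm = ConfusionMatrix.from_predictions(y, p)
    recall_pos = cm.tp / (cm.tp + cm.fn)
    recall_neg = cm.tn / (cm.tn + cm.fp)
    return 0.5 * (recall_pos + recall_neg)


@dataclass
class PRCurve:
    """Precision-recall points swept over descending score thresholds.

    The leading point uses the precision = 1 convention for an empty
    prediction set; ``endpoint_convention`` flags it.
    """
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    endpoint_convention: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "precision": self.precision,
                             "recall": self.recall})


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> PRCurve:
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("PR curve needs both classes in the labels")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_y = y[order]
    n_pos = int(y.sum())
    tp = np.cumsum(sorted_y)
    fp = np.cumsum(1 - sorted_y)
    # keep one point per unique threshold (the last index of each run)
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), sorted_scores.size - 1]
    prec = tp[distinct] / (tp[distinct] + fp[distinct])
    rec = tp[distinct] / n_pos
    thr = sorted_scores[distinct]
    # leading endpoint: threshold above every score, nothing predicted positive
    prec = np.r_[1.0, prec]
    rec = np.r_[0.0, rec]
    thr = np.r_[np.inf, thr]
    return PRCurve(precision=prec, recall=rec, thresholds=thr)


@dataclass
class SplitPlan:
    """record_id → split assignment with population provenance."""
    assignments: dict[str, str]
    population_split: dict[str, str]
    seed: int

    def records(self, split: str) -> list[str]:
        return [rid for rid, s in self.assignments.items() if s == split]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"record_id": list(self.assignments),
                             "split": list(self.assignments.values())})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = -1) -> "SplitPlan":
        return cls(assignments=dict(zip(frame["record_id"], frame["split"])),
                   population_split={}, seed=seed)


def population_split(manifest: pd.DataFrame, seed: int,
                     val_frac: float = 0.2) -> SplitPlan:
    """Assign whole populations to train+validation or test, then 80/20.

    Per species the single largest population goes to the train side (ties
    broken by population id) and every other population to the test side,
    so no population ever straddles the boundary. Records with species
    ``unknown`` (false triggers) are left out of the plan.
    """
    labeled = manifest[manifest["species"].isin([POSITIVE, NEGATIVE])]
    population_assignment: dict[str, str] = {}
    for species, group in labeled.groupby("species"):
        sizes = group.groupby("population").size()
        if len(sizes) < 2:
            raise ValueError(
                f"species {species} has a single population; a population-wise "
                "split needs at least two")
        # largest population trains; ties resolved by id for determinism
        train_pop = min(sizes.index[sizes == sizes.max()])
        for pop in sizes.index:
            population_assignment[pop] = "train" if pop == train_pop else "test"

    assignments: dict[str, str] = {}
    train_side = labeled[labeled["population"].map(population_assignment) == "train"]
    test_side = labeled[labeled["population"].map(population_assignment) == "test"]
    rng = np.random.default_rng(seed)
    ids = train_side["record_id"].to_numpy()
    n_val = int(round(val_frac * ids.size))
    val_ids = set(rng.choice(ids, size=n_val, replace=False))
    for rid in ids:
        assignments[rid] = "validation" if rid in val_ids else "train"
    for rid in test_side["record_id"]:
        assignments[rid] = "test"
    return SplitPlan(assignments=assignments,
                     population_split=population_assignment, seed=seed)


@dataclass
class EvalReport:
    balanced_accuracy: float
    f1: float
    precision: float
    recall: float
    threshold: float
    confusion: ConfusionMatrix
    curve: PRCurve
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "threshold": self.threshold,
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "tn": self.confusion.tn, "fn": self.confusion.fn},
            "flags": self.flags,
        }


def evaluate_scores(scores: np.ndarray, labels: np.ndarray,
                    threshold: float) -> EvalReport:
    """Metrics from raw scores: hard labels at ``score >= threshold``."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if scores.size == 0:
        raise ValueError("empty evaluation set")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    preds = (scores >= threshold).astype(int)
    cm = ConfusionMatrix.from_predictions(y, preds)
    flags: list[str] = []
    try:
        p = precision(cm)
    except ZeroDivisionError:
        p, flags = 0.0, flags + ["precision undefined (no positive predictions); reported as 0"]
    try:
        r = recall(cm)
    except ZeroDivisionError:
        r, flags = 0.0, flags + ["recall undefined (no positive labels); reported as 0"]
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return EvalReport(balanced_accuracy=balanced_accuracy(y, preds), f1=f,
                      precision=p, recall=r, threshold=threshold, confusion=cm,
                      curve=pr_curve(scores, y), flags=flags)


def evaluate_model(model, threshold: float, x: np.ndarray,
                   labels: np.ndarray) -> EvalReport:
    """Run a trained classifier on a test set and report its metrics."""
    if x.shape[0] == 0:
        raise ValueError("empty test set")
    scores = model.predict_proba(x)
    return evaluate_scores(scores, labels, threshold)
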