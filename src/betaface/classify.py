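"""Single-feature threshold classification and its evaluation.

Each interface is reduced to one score (avgΣB, ΔASA, ...), and a decision
threshold is learned on a labelled training set: every midpoint between
consecutive distinct scores is a candidate split, each split is scored by
MCC in both decision directions, the splits reaching the top 10% of
performances are collected and their average becomes the threshold.
Averaging the best decile rather than taking the single best split
stabilizes the cutoff against sampling noise.

For positives-only training data (affinity-annotated complexes with no
packing negatives) the threshold is instead a low quantile of the score
distribution — by default the 25% quantile.

Biological complexes are the positive class throughout; direction encodes
whether high or low scores vote "biological" (ΔASA is
positive-is-biological, the B-factor features negative-is-biological).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoredInterface",
    "ThresholdModel",
    "EvalMetrics",
    "metrics",
    "optimal_threshold",
    "quantile_threshold",
    "cross_dataset_eval",
]

POSITIVE = "biological"
NEGATIVE = "packing"


@dataclass
class ScoredInterface:
    entry_id: str
    feature_name: str
    score: float
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError(f"{self.entry_id}: non-finite score")
        if self.label not in (POSITIVE, NEGATIVE, "unknown"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass
class ThresholdModel:
    """A learned split: scores on the ``direction`` side are biological."""

    feature_name: str
    threshold: float
    direction: str  # "positive-is-biological" | "negative-is-biological"
    top_fraction: float = 0.10
    candidate_splits_used: list[float] = field(default_factory=list)
    train_mcc: float = float("nan")

    def predict(self, scores: Iterable[float]) -> np.ndarray:
        s = np.asarray(list(scores), dtype=float)
        if self.direction == "positive-is-biological":
            return s > self.threshold
        return s < self.threshold

    def to_dict(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "threshold": self.threshold,
            "direction": self.direction,
            "top_fraction": self.top_fraction,
            "candidate_splits_used": list(self.candidate_splits_used),
            "train_mcc": self.train_mcc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModel":
        return cls(**d)


@dataclass
class EvalMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    specificity: float
    accuracy: float
    mcc: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics(predictions: Sequence[bool], labels: Sequence[bool]) -> EvalMetrics:
    """Confusion counts plus precision/recall/specificity/accuracy/MCC.

    ``labels`` are True for biological binding (the positive class).  A
    zero denominator in MCC yields 0, the usual degenerate-predictor
    convention.
    """
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int((pred & lab).sum())
    fp = int((pred & ~lab).sum())
    tn = int((~pred & ~lab).sum())
    fn = int((~pred & lab).sum())
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, denom)
    return EvalMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=_safe_div(tp, tp + fp),
        recall=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        accuracy=_safe_div(tp + tn, tp + fp + tn + fn),
        mcc=mcc,
    )


def _mcc_curves(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MCC at every midpoint split, for both directions, vectorized.

    Returns (splits, mcc_positive_is_biological, mcc_negative_is_biological).
    """
    order = np.argsort(scores, kind="mergesort")
    s = scores[order]
    y = labels[order].astype(float)
    distinct = np.flatnonzero(np.diff(s) > 0)
    if len(distinct) == 0:
        raise ValueError("all scores identical; no candidate splits")
    splits = (s[distinct] + s[distinct + 1]) / 2.0
    P = y.sum()
    N = len(y) - P
    cum_pos = np.cumsum(y)[distinct]          # positives with score <= split
    cum_n = distinct + 1.0                    # items with score <= split
    # direction: positive-is-biological (predict score > t)
    tp = P - cum_pos
    fp = (N - (cum_n - cum_pos))
    fn = cum_pos
    tn = cum_n - cum_pos
    mcc_pos = _vector_mcc(tp, fp, tn, fn)
    # direction: negative-is-biological (predict score < t)
    mcc_neg = _vector_mcc(cum_pos, cum_n - cum_pos, fp, tp)
    return splits, mcc_pos, mcc_neg


def _vector_mcc(tp, fp, tn, fn):
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(divide="ignore", invalid="ignore"):
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / np.where(denom > 0, denom, 1.0), 0.0)
    return mcc


def optimal_threshold(scored: Sequence[ScoredInterface],
                      top_fraction: float = 0.10,
                      mode: str = "top_decile") -> ThresholdModel:
    """Learn a split threshold by top-decile MCC averaging.

    Candidate splits are midpoints between consecutive distinct sorted
    scores.  Each split is assigned its best-direction MCC; the top
    ``ceil(top_fraction · n_splits)`` splits (MCC ties at the cut all
    included) are averaged into the threshold, and the decision direction
    is the majority direction among them.  ``mode="within_best"``
    instead keeps every split whose MCC is within ``top_fraction`` of
    the best value.
    """
    if len(scored) < 10:
        raise ValueError("need at least 10 scored interfaces")
    names = {s.feature_name for s in scored}
    if len(names) > 1:
        raise ValueError(f"mixed feature names: {sorted(names)}")
    scores = np.array([s.score for s in scored])
    labels = np.array([s.label == POSITIVE for s in scored])
    if labels.all() or not labels.any():
        raise ValueError("training data must contain both classes")
    splits, mcc_pos, mcc_neg = _mcc_curves(scores, labels)
    best = np.maximum(mcc_pos, mcc_neg)
    if mode == "top_decile":
        k = max(1, math.ceil(top_fraction * len(splits)))
        cutoff = np.sort(best)[::-1][k - 1]
    elif mode == "within_best":
        cutoff = best.max() - top_fraction * abs(best.max())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = best >= cutoff - 1e-12
    kept_splits = splits[keep]
    n_pos_dir = int((mcc_pos[keep] >= mcc_neg[keep]).sum())
    direction = ("positive-is-biological"
                 if n_pos_dir * 2 > keep.sum()
                 or (n_pos_dir * 2 == keep.sum()
                     and mcc_pos[keep].max() >= mcc_neg[keep].max())
                 else "negative-is-biological")
    model = ThresholdModel(
        feature_name=next(iter(names)),
        threshold=float(kept_splits.mean()),
        direction=direction,
        top_fraction=top_fraction,
        candidate_splits_used=[float(x) for x in kept_splits],
    )
    model.train_mcc = metrics(model.predict(scores), labels).mcc
    return model


def quantile_threshold(scored: Sequence[ScoredInterface], q: float = 0.25,
                       direction: str = "negative-is-biological") -> ThresholdModel:
    """Quantile threshold from positives-only data.

    Used when only true complexes are available: the threshold is the
    empirical ``q``-quantile (linear interpolation) of their scores, and
    the caller supplies the feature's polarity.
    """
    if not scored:
        raise ValueError("empty training data")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if any(s.label == NEGATIVE for s in scored):
        raise ValueError("quantile_threshold expects positives only")
    names = {s.feature_name for s in scored}
    if len(names) > 1:
        raise ValueError(f"mixed feature names: {sorted(names)}")
    scores = np.array([s.score for s in scored])
    return ThresholdModel(
        feature_name=next(iter(names)),
        threshold=float(np.quantile(scores, q)),
        direction=direction,
        top_fraction=q,
        candidate_splits_used=[],
    )


def evaluate(model: ThresholdModel, scored: Sequence[ScoredInterface]) -> EvalMetrics:
    scores = [s.score for s in scored]
    labels = [s.label == POSITIVE for s in scored]
    return metrics(model.predict(scores), labels)


def cross_dataset_eval(train: Sequence[ScoredInterface],
                       tests: dict[str, Sequence[ScoredInterface]],
                       train_name: str = "train",
                       quantile_q: float = 0.25,
                       quantile_direction: str = "negative-is-biological") -> pd.DataFrame:
    """Fit once on ``train``, apply unchanged to every test set.

    Positives-only training data automatically falls back to the
    quantile rule.  Returns one row per (train, test) with the fitted
    threshold and all evaluation metrics.
    """
    has_neg = any(s.label == NEGATIVE for s in train)
    if has_neg:
        model = optimal_threshold(train)
    else:
        model = quantile_threshold(train, q=quantile_q,
                                   direction=quantile_direction)
    rows = []
    for name, ds in tests.items():
        m = evaluate(model, ds)
        rows.append({
            "train": train_name, "test": name,
            "feature": model.feature_name,
            "threshold": model.threshold, "direction": model.direction,
            **m.as_dict(),
        })
    return pd.DataFrame(rows)
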