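"""Operating points, ROC/AUC, Youden-index selection, and instruments.

All classification rules here are of the form "positive iff score >= t".
For a two-item logistic model the scores take at most 16 distinct values
(one per response pattern), so ties are pervasive; AUC is therefore defined
in the tie-corrected rank (Mann-Whitney) form, the probability that a random
positive outscores a random negative, counting ties as 1/2.  That form is
unambiguous on heavily tied data and equals the trapezoidal area under the
ROC polygon over the distinct score values.

An :class:`Instrument` is a frozen, deployable rule: either a pair model
with one chosen probability threshold, or a classical sum-score cutoff.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .pair_model import PairModel


class MetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


@dataclass(frozen=True)
class OperatingPoint:
    """One decision rule's threshold and its exact confusion-count metrics.

    ``ppv``/``npv`` are ``None`` (flagged undefined) when their denominator
    is zero, never silently 0.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    @property
    def ppv(self) -> Optional[float]:
        return None if self.tp + self.fp == 0 else self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return None if self.tn + self.fn == 0 else self.tn / (self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden": self.youden,
            "ppv": self.ppv,
            "npv": self.npv,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> OperatingPoint:
    """Exact confusion counts for the rule "positive iff score >= threshold"."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return OperatingPoint(threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn)


def operating_points(
    scores: Sequence[float], labels: Sequence[bool], thresholds: Sequence[float]
) -> list[OperatingPoint]:
    """One operating point per threshold; requires both classes present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(scores) != len(labels):
        raise MetricError(f"scores ({len(scores)}) and labels ({len(labels)}) differ in length")
    if labels.all() or not labels.any():
        raise MetricError("labels contain a single class; sensitivity/specificity undefined")
    return [confusion_at(scores, labels, t) for t in thresholds]


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Tie-corrected rank AUC: P(score_pos > score_neg) + P(tie)/2.

    Computed from midranks (the Mann-Whitney U statistic normalised by
    n_pos * n_neg), which handles the pervasive ties of a 16-value score
    exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC undefined: labels contain a single class")
    ranks = rankdata(scores)  # midranks
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def candidate_thresholds(model: PairModel) -> list[float]:
    """Distinct pattern probabilities of a pair model, descending.

    With all 16 probabilities distinct this is the full 16-entry threshold
    menu; coincident probabilities (e.g. equal weights) merge.
    """
    probs = np.array(list(model.pattern_probabilities().values()))
    return list(np.unique(probs)[::-1])


def select_youden_threshold(points: Sequence[OperatingPoint]) -> OperatingPoint:
    """The operating point maximising Youden's J = sens + spec - 1.

    Ties are broken toward higher sensitivity (the rule-out convention for
    prescreening), then toward the lower threshold for determinism.
    """
    if not points:
        raise MetricError("select_youden_threshold requires a nonempty candidate list")
    return max(points, key=lambda p: (p.youden, p.sensitivity, -p.threshold))


def predictive_values(point: OperatingPoint, prevalence: float) -> tuple[Optional[float], Optional[float]]:
    """PPV and NPV at an external prevalence via Bayes' rule.

    ppv = sens*pi / (sens*pi + (1-spec)*(1-pi));
    npv = spec*(1-pi) / (spec*(1-pi) + (1-sens)*pi).
    Zero denominators yield ``None`` (flagged undefined).
    """
    if not 0.0 < prevalence < 1.0:
        raise MetricError(f"prevalence must be in (0, 1), got {prevalence}")
    sens, spec = point.sensitivity, point.specificity
    ppv_den = sens * prevalence + (1.0 - spec) * (1.0 - prevalence)
    npv_den = spec * (1.0 - prevalence) + (1.0 - sens) * prevalence
    ppv = None if ppv_den == 0 else sens * prevalence / ppv_den
    npv = None if npv_den == 0 else spec * (1.0 - prevalence) / npv_den
    return ppv, npv


def sum_score_points(data: pd.DataFrame, items: Sequence[int]) -> list[OperatingPoint]:
    """Operating points of the classical sum-score cutoff family.

    For item subset S the candidate rules are "subscore >= c" for integer
    cutoffs c in {0, ..., 3|S|}; for two items this is exactly the 7-rule
    menu of an unweighted 0-6 subscale.
    """
    items = list(items)
    if not items:
        raise MetricError("sum_score_points requires a nonempty item set")
    cols = [f"item{i}" for i in items]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise MetricError(f"data lacks item columns: {missing}")
    subscore = data[cols].sum(axis=1).to_numpy(dtype=float)
    labels = data["label"].to_numpy(dtype=bool)
    cutoffs = range(0, 3 * len(items) + 1)
    return operating_points(subscore, labels, list(cutoffs))


# ---------------------------------------------------------------------------
# ROC curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCCurve:
    """Ordered operating points from the all-positive to the all-negative rule."""

    points: tuple[OperatingPoint, ...]
    auc: float

    def trapezoid_area(self) -> float:
        """Area under the (FPR, TPR) polygon; equals the rank AUC."""
        fpr = np.array([1.0 - p.specificity for p in self.points])
        tpr = np.array([p.sensitivity for p in self.points])
        return float(-np.trapezoid(tpr, fpr))  # points run from (1,1) to (0,0)


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    """ROC over all distinct score thresholds, anchored at both trivial rules."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    distinct = np.unique(scores)
    thresholds = list(distinct)  # ascending: most permissive rule first
    pts = operating_points(scores, labels, thresholds)
    # close the curve with the all-negative rule (threshold above max score)
    closing = confusion_at(scores, labels, float(distinct[-1]) + 1.0)
    pts = pts + [closing]
    return ROCCurve(points=tuple(pts), auc=auc(scores, labels))


# ---------------------------------------------------------------------------
# Frozen instruments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Instrument:
    """A frozen, deployable classifier: pattern scores plus one fixed threshold.

    ``kind`` is ``"model"`` (a :class:`PairModel` with a probability
    threshold) or ``"sum_score"`` (an unweighted item subset with an integer
    cutoff).  A frozen instrument's predictions depend only on the response
    pattern; evaluation never mutates it.
    """

    kind: str
    threshold: float
    model: Optional[PairModel] = None
    items: Optional[tuple[int, ...]] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "model":
            if self.model is None:
                raise ValueError("model instrument requires a PairModel")
        elif self.kind == "sum_score":
            if not self.items:
                raise ValueError("sum-score instrument requires a nonempty item set")
        else:
            raise ValueError(f"unknown instrument kind {self.kind!r}")

    @property
    def display_label(self) -> str:
        if self.label:
            return self.label
        if self.kind == "model":
            return f"{self.model.pair}>={self.threshold:.3f}"
        items = "&".join(map(str, self.items))
        return f"sum{items}>={int(self.threshold)}"

    def score(self, data: pd.DataFrame) -> np.ndarray:
        if self.kind == "model":
            return self.model.score(data)
        cols = [f"item{i}" for i in self.items]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise MetricError(f"data lacks item columns: {missing}")
        return data[cols].sum(axis=1).to_numpy(dtype=float)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self.score(data) >= self.threshold

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "threshold": self.threshold, "label": self.label}
        if self.kind == "model":
            d["model"] = self.model.to_dict()
        else:
            d["items"] = list(self.items)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Instrument":
        if d["kind"] == "model":
            return cls(
                kind="model",
                threshold=float(d["threshold"]),
                model=PairModel.from_dict(d["model"]),
                label=d.get("label", ""),
            )
        return cls(
            kind="sum_score",
            threshold=float(d["threshold"]),
            items=tuple(int(i) for i in d["items"]),
            label=d.get("label", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Instrument":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable digest of the frozen parameters, for purity checks."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Arrange metric rows in the canonical column order for TSV emission."""
    columns = [
        "instrument", "threshold", "youden", "sensitivity", "specificity",
        "ppv", "npv", "tp", "fp", "tn", "fn",
    ]
    frame = pd.DataFrame(rows)
    ordered = [c for c in columns if c in frame.columns]
    extra = [c for c in frame.columns if c not in columns]
    return frame[ordered + extra]
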