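"""Frozen-instrument evaluation and side-by-side comparison reports.

Frozen instruments are evaluated on held-out or external-style data without
any retraining or threshold adjustment: the report carries the
threshold-free AUC of the instrument's scores plus the full operating point
at the frozen threshold.  Purity is enforced by hashing the instrument
before and after evaluation.  Prevalence is never reweighted across data
sets; predictive values are reported at each data set's own prevalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pipeline import AuditLog
from .roc import Instrument, MetricError, OperatingPoint, auc, confusion_at


@dataclass(frozen=True)
class EvaluationReport:
    """One instrument's performance on one data set."""

    dataset: str
    instrument: str
    auc: float
    point: OperatingPoint
    n: int
    prevalence: float

    def to_row(self) -> dict:
        row = {"dataset": self.dataset, "instrument": self.instrument, "auc": self.auc}
        row.update(self.point.as_dict())
        row["n"] = self.n
        row["prevalence"] = self.prevalence
        return row

    def to_dict(self) -> dict:
        return self.to_row()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EvaluationReport":
        d = json.loads(Path(path).read_text())
        point = OperatingPoint(
            threshold=float(d["threshold"]),
            tp=int(d["tp"]), fp=int(d["fp"]), tn=int(d["tn"]), fn=int(d["fn"]),
        )
        return cls(
            dataset=d["dataset"], instrument=d["instrument"], auc=float(d["auc"]),
            point=point, n=int(d["n"]), prevalence=float(d["prevalence"]),
        )


def evaluate_frozen(
    instrument: Instrument,
    data: pd.DataFrame,
    dataset: str = "dataset",
    audit: Optional[AuditLog] = None,
) -> EvaluationReport:
    """Evaluate a frozen instrument on preprocessed labelled data.

    The instrument is used exactly as frozen — no refitting, no threshold
    adjustment — and is verified unmodified by comparing its content hash
    before and after scoring.
    """
    hash_before = instrument.content_hash()
    scores = instrument.score(data)  # raises if an item column is absent
    labels = data["label"].to_numpy(dtype=bool)
    report = EvaluationReport(
        dataset=dataset,
        instrument=instrument.display_label,
        auc=auc(scores, labels),
        point=confusion_at(scores, labels, instrument.threshold),
        n=len(data),
        prevalence=float(labels.mean()),
    )
    if instrument.content_hash() != hash_before:  # pragma: no cover - frozen dataclass
        raise RuntimeError("instrument mutated during evaluation")
    if audit is not None:
        audit.record("evaluate", dataset, len(data))
    return report


def evaluate_sum_score(
    items: Sequence[int],
    cutoff: int,
    data: pd.DataFrame,
    dataset: str = "dataset",
    audit: Optional[AuditLog] = None,
) -> EvaluationReport:
    """Evaluate the classical sum-score cutoff rule on preprocessed data."""
    instrument = Instrument(kind="sum_score", threshold=float(cutoff), items=tuple(items))
    return evaluate_frozen(instrument, data, dataset=dataset, audit=audit)


def compare_instruments(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """One row per instrument per data set, with best-AUC / best-Youden flags.

    Within each data set, every instrument attaining the maximal AUC is
    flagged ``auc_best`` and likewise for the Youden index, so exact ties
    are visible rather than broken arbitrarily.
    """
    if len(reports) < 2:
        raise MetricError("compare_instruments requires at least two reports")
    by_dataset: dict[str, list[EvaluationReport]] = {}
    for r in reports:
        by_dataset.setdefault(r.dataset, []).append(r)
    rows = []
    for dataset, group in by_dataset.items():
        max_auc = max(r.auc for r in group)
        max_youden = max(r.point.youden for r in group)
        for r in group:
            row = r.to_row()
            row["auc_best"] = bool(np.isclose(r.auc, max_auc))
            row["youden_best"] = bool(np.isclose(r.point.youden, max_youden))
            rows.append(row)
    return pd.DataFrame(rows)


def write_comparison(frame: pd.DataFrame, path: str | Path) -> None:
    """Emit a comparison table as TSV, metrics printed at 3 decimals."""
    out = frame.copy()
    for col in ("auc", "threshold", "youden", "sensitivity", "specificity", "ppv", "npv"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)
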