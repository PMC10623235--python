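"""End-to-end study procedure for exhaustive two-item subscale selection.

The pipeline mirrors a standard instrument-development design:

1. one stratified train/test split of the labelled data (default 70/30);
2. stratified 5-fold cross-validation on the training split;
3. per pairing, a deterministic regularization search scored by mean
   cross-validated AUC;
4. ranking of all 36 item pairings by mean CV AUC;
5. freezing of a chosen pairing: final model fitted on the full training
   split, decision threshold chosen from the model's 16-pattern lattice by
   maximum mean cross-validated Youden index.

Everything downstream of the split sees only the training rows until a
frozen instrument is finally evaluated; an audit log records each data
access with its stage so leakage is checkable after the fact.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pair_model import ItemPair, PairModel, all_pairs, fit_pair_model
from .roc import auc, candidate_thresholds, confusion_at


class PipelineError(RuntimeError):
    """Raised when the study procedure cannot proceed (bad strata, fold failures)."""


@dataclass
class AuditLog:
    """Append-only record of data accesses, tagged by pipeline stage."""

    entries: list[dict] = field(default_factory=list)

    def record(self, stage: str, dataset: str, n_rows: int) -> None:
        self.entries.append(
            {"stage": stage, "dataset": dataset, "n_rows": int(n_rows), "time": time.time()}
        )

    def stages_for(self, dataset: str) -> list[str]:
        return [e["stage"] for e in self.entries if e["dataset"] == dataset]


@dataclass(frozen=True)
class CVPlan:
    """A stratified k-fold assignment of training rows.

    ``fold_of`` maps positional row index within the training table to a
    fold id in 0..k-1; folds partition the rows, and within each label
    stratum fold sizes differ by at most one.
    """

    k: int
    fold_of: np.ndarray
    seed: int
    stratified: bool = True

    def validation_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def training_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass(frozen=True)
class TuningConfig:
    """Deterministic regularization search settings.

    The penalty scale is searched on a log grid spanning ``search_space``
    (default six orders of magnitude), then refined once around the
    incumbent; the tuned value is the argmax of mean CV AUC over the
    evaluated candidates.
    """

    search_space: tuple[float, float] = (1e-3, 1e3)
    budget: int = 10
    seed: int = 0


@dataclass(frozen=True)
class PairingResult:
    pair: ItemPair
    per_fold_auc: tuple[float, ...]
    mean_cv_auc: float
    tuned_reg: float


def _stratum_indices(labels: np.ndarray) -> dict[bool, np.ndarray]:
    return {value: np.flatnonzero(labels == value) for value in (True, False)}


def split_dataset(
    data: pd.DataFrame,
    train_fraction: float,
    seed: int,
    audit: Optional[AuditLog] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split with exact largest-remainder sizing.

    The total training size is round(train_fraction * n); it is allocated
    across the two label strata by largest fractional remainder, so both the
    overall and per-stratum sizes are fixed by (n, fraction) alone.  Row
    membership is randomised by the seed; the output tables preserve the
    input row order.
    """
    if not 0.0 < train_fraction < 1.0:
        raise PipelineError(f"train_fraction must be in (0, 1), got {train_fraction}")
    labels = data["label"].to_numpy(dtype=bool)
    strata = _stratum_indices(labels)
    for value, idx in strata.items():
        if len(idx) < 2:
            raise PipelineError(
                f"stratum label={value} has only {len(idx)} rows; cannot split"
            )
    n = len(data)
    n_train = int(round(train_fraction * n))
    exact = {v: train_fraction * len(idx) for v, idx in strata.items()}
    alloc = {v: int(np.floor(e)) for v, e in exact.items()}
    remainders = sorted(exact, key=lambda v: exact[v] - alloc[v], reverse=True)
    shortfall = n_train - sum(alloc.values())
    for v in remainders[:shortfall]:
        alloc[v] += 1

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    train_mask = np.zeros(n, dtype=bool)
    for value, idx in strata.items():
        chosen = rng.permutation(idx)[: alloc[value]]
        train_mask[chosen] = True
    train = data.loc[train_mask].copy()
    test = data.loc[~train_mask].copy()
    if audit is not None:
        audit.record("split", "train", len(train))
        audit.record("split", "test", len(test))
    return train, test


def make_cv_folds(train: pd.DataFrame, k: int = 5, seed: int = 0) -> CVPlan:
    """Stratified k-fold partition of the training rows.

    Within each label stratum the shuffled members are dealt to folds as
    evenly as possible; the fold receiving each stratum's remainder rotates
    across strata so overall fold sizes also differ by at most one.
    """
    if k < 2:
        raise PipelineError(f"k must be >= 2, got {k}")
    labels = train["label"].to_numpy(dtype=bool)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    fold_of = np.full(len(train), -1, dtype=np.int64)
    offset = 0
    for value, idx in _stratum_indices(labels).items():
        if len(idx) < k:
            raise PipelineError(
                f"stratum label={value} has {len(idx)} rows, fewer than k={k}"
            )
        shuffled = rng.permutation(idx)
        q, r = divmod(len(shuffled), k)
        sizes = np.full(k, q, dtype=np.int64)
        extras = [(offset + t) % k for t in range(r)]
        sizes[extras] += 1
        offset += r
        assignment = np.repeat(np.arange(k), sizes)
        fold_of[shuffled] = assignment
    return CVPlan(k=k, fold_of=fold_of, seed=seed)


def _cv_fold_aucs(
    train: pd.DataFrame, plan: CVPlan, pair: ItemPair, reg_strength: float
) -> list[float]:
    """Per-fold validation AUC for one penalty value."""
    fold_aucs = []
    for fold in range(plan.k):
        fit_rows = train.iloc[plan.training_indices(fold)]
        val_rows = train.iloc[plan.validation_indices(fold)]
        try:
            model = fit_pair_model(fit_rows, pair, reg_strength)
            fold_auc = auc(model.score(val_rows), val_rows["label"].to_numpy(dtype=bool))
        except Exception as exc:
            raise PipelineError(
                f"CV fold {fold} failed for {pair} at reg_strength={reg_strength:g}: {exc}"
            ) from exc
        fold_aucs.append(fold_auc)
    return fold_aucs


def tune_regularization(
    train: pd.DataFrame,
    plan: CVPlan,
    pair: ItemPair,
    tuning: TuningConfig = TuningConfig(),
) -> tuple[float, list[float]]:
    """Pick the penalty scale maximising mean CV AUC over a deterministic ladder.

    Stage one evaluates a log-spaced grid across the search space; stage two
    spends the remaining budget on a finer log grid one ladder step either
    side of the incumbent.  Returns the argmax over all evaluated candidates
    (global optimality is not claimed) and its per-fold AUCs.

    Mean CV AUC is a rank statistic, so candidates whose fits differ only by
    proportional weight shrinkage tie exactly; ties are broken toward the
    weaker penalty (larger scale), which keeps the 16 pattern probabilities
    spread out rather than compressed toward the prevalence.
    """
    if tuning.budget < 1:
        raise PipelineError(f"budget must be >= 1, got {tuning.budget}")
    lo, hi = tuning.search_space
    if lo <= 0 or hi <= 0 or lo > hi:
        raise PipelineError(f"invalid search space {tuning.search_space}")

    n_first = 1 if tuning.budget == 1 else max(2, (tuning.budget + 1) // 2)
    ladder = list(np.geomspace(lo, hi, n_first))
    evaluated: dict[float, list[float]] = {}

    def evaluate(c: float) -> None:
        c = float(c)
        if c not in evaluated:
            evaluated[c] = _cv_fold_aucs(train, plan, pair, c)

    for c in ladder:
        evaluate(c)

    def incumbent() -> float:
        return min(
            evaluated,
            key=lambda c: (-float(np.mean(evaluated[c])), -c),
        )

    remaining = tuning.budget - len(evaluated)
    if remaining > 0 and len(ladder) > 1:
        best = incumbent()
        step = ladder[1] / ladder[0]
        refine = np.geomspace(best / step, best * step, remaining + 2)[1:-1]
        for c in refine:
            if len(evaluated) >= tuning.budget:
                break
            evaluate(float(np.clip(c, lo, hi)))

    best = incumbent()
    return best, evaluated[best]


def rank_pairings(
    train: pd.DataFrame,
    plan: CVPlan,
    tuning: TuningConfig = TuningConfig(),
    audit: Optional[AuditLog] = None,
) -> list[PairingResult]:
    """Tune and score every one of the 36 item pairings; rank by mean CV AUC.

    Ties in mean CV AUC are broken by lexicographic pair order so the
    ranking is a deterministic function of (data, plan, tuning).
    """
    results = []
    for pair in all_pairs():
        tuned_reg, per_fold = tune_regularization(train, plan, pair, tuning)
        results.append(
            PairingResult(
                pair=pair,
                per_fold_auc=tuple(per_fold),
                mean_cv_auc=float(np.mean(per_fold)),
                tuned_reg=tuned_reg,
            )
        )
    if audit is not None:
        audit.record("cv_ranking", "train", len(train))
    results.sort(key=lambda r: (-r.mean_cv_auc, r.pair))
    return results


def rankings_frame(results: Sequence[PairingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair": [str(r.pair) for r in results],
            "mean_cv_auc": [r.mean_cv_auc for r in results],
            "tuned_reg": [r.tuned_reg for r in results],
            **{
                f"fold{f}_auc": [r.per_fold_auc[f] for r in results]
                for f in range(len(results[0].per_fold_auc))
            },
        }
    )


def finalize_instrument(
    train: pd.DataFrame,
    plan: CVPlan,
    pair: ItemPair,
    tuned_reg: float,
    audit: Optional[AuditLog] = None,
):
    """Fit the final pair model and freeze its CV-Youden-optimal threshold.

    The final model is fitted on the full training split.  Its candidate
    decision rules are the distinct pattern-probability thresholds — each a
    partition of the 16-pattern lattice into predicted-positive and
    predicted-negative cells.  Because a rule depends only on the response
    pattern, each can be scored on every CV validation fold without
    reference to fold-model probabilities; the rule with maximal mean CV
    Youden index wins, ties going to higher mean sensitivity and then to the
    lower threshold.  Returns the frozen :class:`~pairscreen.roc.Instrument`.
    """
    from .roc import Instrument  # local import to avoid cycle at module load

    model = fit_pair_model(train, pair, tuned_reg)
    thresholds = candidate_thresholds(model)
    scores = model.score(train)
    labels = train["label"].to_numpy(dtype=bool)

    best = None
    for threshold in thresholds:
        sens, spec = [], []
        for fold in range(plan.k):
            val_idx = plan.validation_indices(fold)
            point = confusion_at(scores[val_idx], labels[val_idx], threshold)
            if point.tp + point.fn == 0 or point.tn + point.fp == 0:
                raise PipelineError(
                    f"fold {fold} has a single class; cannot score threshold {threshold:g}"
                )
            sens.append(point.sensitivity)
            spec.append(point.specificity)
        mean_sens, mean_spec = float(np.mean(sens)), float(np.mean(spec))
        key = (mean_sens + mean_spec - 1.0, mean_sens, -threshold)
        if best is None or key > best[0]:
            best = (key, threshold)
    if audit is not None:
        audit.record("finalize", "train", len(train))
    return Instrument(kind="model", threshold=float(best[1]), model=model)
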