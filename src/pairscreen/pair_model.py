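"""Regularized logistic models on a pair of ordinal questionnaire items.

A pair model scores the 4x4 lattice of joint responses (a, b) of two 0-3
items with

    z = w1 * a + w2 * b + bias,        p = sigmoid(z),

the probability of screen positivity.  Because the input space has only 16
patterns, the full model is equivalently a 16-entry pattern -> probability
table, which is always rederived from (w1, w2, bias) and never cached.

Fitting minimises the penalized objective

    mean negative log-likelihood + (w1^2 + w2^2) / (2 * reg_strength)

with the bias unpenalized so it can absorb class prevalence.  Larger
``reg_strength`` means a weaker penalty (the inverse-penalty convention).
The objective is strictly convex, so the optimum is unique; it is found by
damped Newton iteration on the 16 pattern sufficient statistics and declared
converged only when the gradient norm drops below 1e-8.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .simulate import N_ITEMS

RESPONSE_LEVELS = (0, 1, 2, 3)
#: All 16 joint response patterns of a two-item instrument, in lattice order.
PATTERNS: tuple[tuple[int, int], ...] = tuple(
    itertools.product(RESPONSE_LEVELS, RESPONSE_LEVELS)
)

GRADIENT_TOL = 1e-8
_MAX_NEWTON_ITER = 200


class FitError(RuntimeError):
    """Raised when a pair model cannot be fitted (bad data or non-convergence)."""


class ItemPair(NamedTuple):
    """An unordered pair of item indices, stored with i < j."""

    i: int
    j: int

    @classmethod
    def of(cls, i: int, j: int) -> "ItemPair":
        if i == j:
            raise ValueError(f"pair items must be distinct, got ({i}, {j})")
        if not (1 <= i <= N_ITEMS and 1 <= j <= N_ITEMS):
            raise ValueError(f"item indices must be in 1..{N_ITEMS}, got ({i}, {j})")
        return cls(min(i, j), max(i, j))

    @property
    def columns(self) -> tuple[str, str]:
        return f"item{self.i}", f"item{self.j}"

    def __str__(self) -> str:
        return f"phq{self.i}&{self.j}"


def all_pairs() -> Iterator[ItemPair]:
    """The C(9,2) = 36 distinct item pairs in lexicographic order."""
    for i in range(1, N_ITEMS + 1):
        for j in range(i + 1, N_ITEMS + 1):
            yield ItemPair(i, j)


@dataclass(frozen=True)
class PairModel:
    """A fitted two-item logistic classifier."""

    pair: ItemPair
    w1: float
    w2: float
    bias: float
    reg_strength: float

    def logit(self, a, b):
        return self.w1 * np.asarray(a) + self.w2 * np.asarray(b) + self.bias

    def pattern_probabilities(self) -> dict[tuple[int, int], float]:
        """Probability of screen positivity for each of the 16 response patterns.

        Always recomputed from the parameters so a serialized model can never
        desynchronize from its table.
        """
        return {
            (a, b): float(expit(self.logit(a, b))) for a, b in PATTERNS
        }

    def predict_probability(self, response: tuple[int, int]) -> float:
        a, b = response
        if a not in RESPONSE_LEVELS or b not in RESPONSE_LEVELS:
            raise ValueError(f"responses must be in {RESPONSE_LEVELS}, got {response}")
        return float(expit(self.logit(a, b)))

    def score(self, data: pd.DataFrame) -> np.ndarray:
        """Per-respondent probability scores for a labelled or raw complete table."""
        col_i, col_j = self.pair.columns
        for col in (col_i, col_j):
            if col not in data.columns:
                raise ValueError(f"data lacks required item column {col!r}")
        a = data[col_i].to_numpy(dtype=float)
        b = data[col_j].to_numpy(dtype=float)
        return expit(self.w1 * a + self.w2 * b + self.bias)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pair": [self.pair.i, self.pair.j],
            "w1": self.w1,
            "w2": self.w2,
            "b": self.bias,
            "reg_strength": self.reg_strength,
            # derived, for human inspection only; ignored on load
            "pattern_table": {
                f"{a},{b}": p for (a, b), p in self.pattern_probabilities().items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairModel":
        return cls(
            pair=ItemPair.of(*d["pair"]),
            w1=float(d["w1"]),
            w2=float(d["w2"]),
            bias=float(d["b"]),
            reg_strength=float(d["reg_strength"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PairModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def pattern_counts(data: pd.DataFrame, pair: ItemPair) -> tuple[np.ndarray, np.ndarray]:
    """Sufficient statistics: positive/negative counts for each of 16 patterns.

    Rows are binned by their (item_i, item_j) response pattern; the logistic
    likelihood depends on the data only through these 32 counts.
    """
    col_i, col_j = pair.columns
    a = data[col_i].to_numpy(dtype=np.int64)
    b = data[col_j].to_numpy(dtype=np.int64)
    y = data["label"].to_numpy(dtype=bool)
    idx = a * 4 + b
    n_pos = np.bincount(idx[y], minlength=16).astype(float)
    n_neg = np.bincount(idx[~y], minlength=16).astype(float)
    return n_pos, n_neg


def penalized_objective(
    params: np.ndarray, n_pos: np.ndarray, n_neg: np.ndarray, reg_strength: float
) -> float:
    """Mean negative log-likelihood plus the L2 weight penalty, from pattern counts."""
    w1, w2, b = params
    pat = np.array(PATTERNS, dtype=float)
    z = w1 * pat[:, 0] + w2 * pat[:, 1] + b
    n = n_pos.sum() + n_neg.sum()
    # log sigma(z) = -log(1+e^-z); log(1-sigma(z)) = -log(1+e^z)
    nll = np.sum(n_pos * np.logaddexp(0.0, -z) + n_neg * np.logaddexp(0.0, z)) / n
    return float(nll + (w1 ** 2 + w2 ** 2) / (2.0 * reg_strength))


def _objective_grad_hess(params, n_pos, n_neg, reg_strength):
    w1, w2, b = params
    pat = np.array(PATTERNS, dtype=float)
    x = np.column_stack([pat[:, 0], pat[:, 1], np.ones(len(pat))])
    z = x @ params
    n = n_pos.sum() + n_neg.sum()
    m = n_pos + n_neg
    p = expit(z)
    obj = np.sum(n_pos * np.logaddexp(0.0, -z) + n_neg * np.logaddexp(0.0, z)) / n
    obj += (w1 ** 2 + w2 ** 2) / (2.0 * reg_strength)
    grad = x.T @ (m * p - n_pos) / n + np.array([w1, w2, 0.0]) / reg_strength
    w = m * p * (1.0 - p)
    hess = (x.T * w) @ x / n + np.diag([1.0 / reg_strength, 1.0 / reg_strength, 0.0])
    return obj, grad, hess


def fit_pair_model(data: pd.DataFrame, pair: ItemPair, reg_strength: float) -> PairModel:
    """Fit the penalized two-item logistic model on a labelled data set.

    The objective is strictly convex in the weights (L2 penalty) and, with
    both classes present, in the bias; damped Newton iteration from the
    prevalence-matched intercept converges in a handful of steps.
    Convergence is declared only when the gradient norm is below 1e-8;
    anything else raises, never a silent partial fit.
    """
    if reg_strength <= 0:
        raise ValueError(f"reg_strength must be positive, got {reg_strength}")
    if "label" not in data.columns:
        raise FitError("data lacks a 'label' column; run score_and_label first")
    n_pos_pat, n_neg_pat = pattern_counts(data, pair)
    n_pos, n_neg = n_pos_pat.sum(), n_neg_pat.sum()
    if n_pos == 0 or n_neg == 0:
        raise FitError(
            f"cannot fit {pair}: data contains a single class "
            f"({int(n_pos)} positive, {int(n_neg)} negative)"
        )

    params = np.array([0.0, 0.0, float(np.log(n_pos / n_neg))])
    for _ in range(_MAX_NEWTON_ITER):
        obj, grad, hess = _objective_grad_hess(params, n_pos_pat, n_neg_pat, reg_strength)
        if np.linalg.norm(grad) < GRADIENT_TOL:
            break
        step = np.linalg.solve(hess, grad)
        if np.linalg.norm(grad) < 1e-5:
            # quadratic-convergence region: objective differences are below
            # float precision, so Armijo tests are meaningless — take the
            # full Newton step
            params = params - step
            continue
        # backtracking keeps the iteration globally convergent
        t = 1.0
        while t > 1e-12:
            candidate = params - t * step
            if penalized_objective(candidate, n_pos_pat, n_neg_pat, reg_strength) <= obj - 1e-4 * t * float(grad @ step):
                break
            t *= 0.5
        params = params - t * step
    else:
        raise FitError(
            f"Newton iteration for {pair} did not reach gradient norm < {GRADIENT_TOL} "
            f"within {_MAX_NEWTON_ITER} iterations"
        )
    w1, w2, b = params
    return PairModel(pair=pair, w1=float(w1), w2=float(w2), bias=float(b), reg_strength=float(reg_strength))


def pattern_probabilities(model: PairModel) -> dict[tuple[int, int], float]:
    """Module-level alias for :meth:`PairModel.pattern_probabilities`."""
    return model.pattern_probabilities()


def predict_probability(model: PairModel, response: tuple[int, int]) -> float:
    """Module-level alias for :meth:`PairModel.predict_probability`."""
    return model.predict_probability(response)
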