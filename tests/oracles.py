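"""Independent reference implementations used only for cross-checking.

Each oracle recomputes a quantity by a route deliberately different from the
package's own: pairwise double loops instead of rank statistics, brute-force
grid refinement instead of Newton iteration, bivariate-normal rectangle
integration instead of sampling.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import multivariate_normal


def auc_double_loop(scores, labels) -> float:
    """AUC as the explicit proportion of (positive, negative) score pairs won."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def confusion_brute_force(scores, labels, threshold):
    """Per-row classification loop; returns (tp, fp, tn, fn)."""
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        pred = s >= threshold
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and y:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def _grid_objective(w1, w2, b, n_pos, n_neg, reg_strength):
    """Penalized objective evaluated on parameter grids (broadcast over last axis)."""
    patterns = np.array(list(itertools.product(range(4), range(4))), dtype=float)
    z = (
        w1[..., None] * patterns[:, 0]
        + w2[..., None] * patterns[:, 1]
        + b[..., None]
    )
    n = n_pos.sum() + n_neg.sum()
    nll = (n_pos * np.logaddexp(0.0, -z) + n_neg * np.logaddexp(0.0, z)).sum(axis=-1) / n
    return nll + (w1 ** 2 + w2 ** 2) / (2.0 * reg_strength)


def grid_search_logistic(n_pos, n_neg, reg_strength, lo=-5.0, hi=5.0, final_step=0.01):
    """Brute-force grid minimisation of the penalized logistic objective.

    Searches [lo, hi]^3 at a coarse step, then repeatedly refines a full grid
    around the incumbent until the step is <= ``final_step``.  The objective
    is convex, so the refinement cannot lose the global minimum region.
    Returns (best_objective, (w1, w2, b)).
    """
    step = 0.5
    centers = (np.arange(lo, hi + step / 2, step),) * 3
    best = None
    while True:
        w1g, w2g, bg = np.meshgrid(*centers, indexing="ij")
        obj = _grid_objective(w1g, w2g, bg, n_pos, n_neg, reg_strength)
        idx = np.unravel_index(np.argmin(obj), obj.shape)
        best = (float(obj[idx]), (float(w1g[idx]), float(w2g[idx]), float(bg[idx])))
        if step <= final_step:
            return best
        new_step = step / 5.0
        centers = tuple(
            np.linspace(c - step, c + step, 11) for c in best[1]
        )
        step = new_step


def bvn_cell_probabilities(cuts_x, cuts_y, rho):
    """Joint 4x4 cell probabilities of two discretised bivariate-normal coordinates.

    Cell (a, b) integrates the unit bivariate normal with correlation ``rho``
    over the rectangle between consecutive cut points.
    """
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    edges_x = np.concatenate([[-np.inf], cuts_x, [np.inf]])
    edges_y = np.concatenate([[-np.inf], cuts_y, [np.inf]])

    def cdf(x, y):
        if np.isinf(x) and x < 0 or np.isinf(y) and y < 0:
            return 0.0
        return float(mvn.cdf([min(x, 1e10), min(y, 1e10)]))

    probs = np.zeros((4, 4))
    for a in range(4):
        for b in range(4):
            probs[a, b] = (
                cdf(edges_x[a + 1], edges_y[b + 1])
                - cdf(edges_x[a], edges_y[b + 1])
                - cdf(edges_x[a + 1], edges_y[b])
                + cdf(edges_x[a], edges_y[b])
            )
    return probs


def spearman_from_joint(probs) -> float:
    """Population Spearman (grade) correlation of a discrete 4x4 joint distribution.

    Each level is assigned its midrank grade F(v-1) + p(v)/2; Spearman with
    midrank ties is the Pearson correlation of the two grade variables.
    """
    probs = np.asarray(probs, dtype=float)
    px = probs.sum(axis=1)
    py = probs.sum(axis=0)

    def grades(p):
        cum = np.concatenate([[0.0], np.cumsum(p)])
        return cum[:-1] + p / 2.0

    gx, gy = grades(px), grades(py)
    ex = float(px @ gx)
    ey = float(py @ gy)
    vx = float(px @ (gx - ex) ** 2)
    vy = float(py @ (gy - ey) ** 2)
    cov = float(((gx[:, None] - ex) * (gy[None, :] - ey) * probs).sum())
    return cov / np.sqrt(vx * vy)
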