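"""Synthetic questionnaire data with the dependence structure of real screening surveys.

Nine ordinal items scored 0-3 are generated from a Gaussian copula: a latent
multivariate-normal "severity" draw is discretised item by item through fixed
cut points chosen so that each item reproduces a configured marginal
distribution.  The copula cleanly separates the marginals (how skewed each
item is) from the dependence (how strongly items move together), which is the
standard construction for simulating correlated Likert responses.

The module also provides
  * prevalence calibration — a single scalar severity offset applied to all
    cut points, found by bisection, so that the screen-positive rate
    P(total >= 10) hits a requested target;
  * a planted "most informative pair" — the latent correlation is rebuilt
    from a one-factor loading model with two chosen items' loadings boosted,
    giving a known ground truth for pairing-recovery experiments;
  * independent per-cell missingness injection.

All randomness flows from explicit integer seeds; identical configurations
produce bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri
from statsmodels.stats.correlation_tools import corr_nearest

N_ITEMS = 9
N_LEVELS = 4
ITEM_COLUMNS = [f"item{k}" for k in range(1, N_ITEMS + 1)]
SCREEN_POSITIVE_CUTOFF = 10

# Sub-stream tags so that each operation draws from its own counter-based
# stream and adding a new operation never perturbs an existing one.
_TAG_GENERATE = 101
_TAG_MISSING = 202
_TAG_CALIBRATE = 303

#: Internal seed for the Monte-Carlo prevalence estimate used during
#: calibration; fixed so the estimate is a pure function of the config.
_CALIBRATION_SEED = 20230917


class SimulationError(ValueError):
    """Raised when a simulation configuration is invalid or unsatisfiable."""


def default_marginals() -> np.ndarray:
    """Skewed-toward-zero response distribution shared by all nine items.

    Community questionnaire samples concentrate mass on "not at all", with a
    long tail into the more symptomatic categories.
    """
    row = np.array([0.58, 0.22, 0.12, 0.08])
    return np.tile(row, (N_ITEMS, 1))


def default_loadings() -> np.ndarray:
    """One-factor loadings giving moderate positive inter-item correlation.

    A common severity factor with loadings of 0.6 yields pairwise latent
    correlations of 0.36, in the range typically reported for general
    population depression questionnaires.
    """
    return np.full(N_ITEMS, 0.6)


def one_factor_correlation(loadings: Sequence[float]) -> np.ndarray:
    """Correlation matrix implied by a single-factor model.

    ``R = L L' + diag(1 - L^2)`` with unit diagonal; valid whenever every
    loading lies in (-1, 1).
    """
    lam = np.asarray(loadings, dtype=float)
    if lam.shape != (N_ITEMS,):
        raise SimulationError(f"expected {N_ITEMS} loadings, got shape {lam.shape}")
    if np.any(np.abs(lam) >= 1.0):
        raise SimulationError(
            f"one-factor loadings must have magnitude < 1, got max {np.abs(lam).max():.4f}"
        )
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic questionnaire sample.

    Parameters
    ----------
    n_respondents:
        Number of rows to generate.
    marginals:
        (9, 4) array; row ``i`` is the probability of responses 0..3 for
        item ``i+1``.  Each row must sum to 1.
    latent_correlation:
        (9, 9) symmetric positive-definite matrix with unit diagonal driving
        the Gaussian copula.
    missing_rate:
        Per-cell independent missingness probability in [0, 1]; applied only
        by :func:`inject_missing`, never by :func:`generate_responses`.
    seed:
        Integer seed; identical configs give bit-identical tables.
    loadings:
        Optional one-factor loadings from which ``latent_correlation`` was
        built.  Required by :func:`plant_informative_pair`.
    planted_pair:
        Optional ``(i, j, boost)`` record of a planted informative pair,
        for provenance only.
    """

    n_respondents: int
    marginals: np.ndarray
    latent_correlation: np.ndarray
    missing_rate: float = 0.0
    seed: int = 0
    loadings: Optional[np.ndarray] = None
    planted_pair: Optional[tuple[int, int, float]] = None

    def __post_init__(self) -> None:
        marg = np.asarray(self.marginals, dtype=float)
        corr = np.asarray(self.latent_correlation, dtype=float)
        object.__setattr__(self, "marginals", marg)
        object.__setattr__(self, "latent_correlation", corr)
        if self.loadings is not None:
            object.__setattr__(self, "loadings", np.asarray(self.loadings, dtype=float))
        if self.n_respondents <= 0:
            raise SimulationError(f"n_respondents must be positive, got {self.n_respondents}")
        if marg.shape != (N_ITEMS, N_LEVELS):
            raise SimulationError(f"marginals must be ({N_ITEMS}, {N_LEVELS}), got {marg.shape}")
        if np.any(marg < 0):
            raise SimulationError("marginals must be nonnegative")
        sums = marg.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise SimulationError(
                f"marginal for item {bad + 1} sums to {sums[bad]:.15f}, not 1 within 1e-12"
            )
        if corr.shape != (N_ITEMS, N_ITEMS):
            raise SimulationError(f"latent_correlation must be ({N_ITEMS}, {N_ITEMS})")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise SimulationError("latent_correlation must be symmetric")
        if np.any(np.abs(np.diag(corr) - 1.0) > 1e-12):
            raise SimulationError("latent_correlation must have unit diagonal")
        min_eig = float(np.linalg.eigvalsh(corr)[0])
        if min_eig <= 0:
            raise SimulationError(
                f"latent_correlation is not positive definite (min eigenvalue {min_eig:.3e})"
            )
        if not 0.0 <= self.missing_rate <= 1.0:
            raise SimulationError(f"missing_rate must be in [0, 1], got {self.missing_rate}")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_respondents": int(self.n_respondents),
            "marginals": self.marginals.tolist(),
            "latent_correlation": self.latent_correlation.tolist(),
            "missing_rate": float(self.missing_rate),
            "seed": int(self.seed),
        }
        if self.loadings is not None:
            d["loadings"] = self.loadings.tolist()
        if self.planted_pair is not None:
            i, j, boost = self.planted_pair
            d["planted_pair"] = [int(i), int(j), float(boost)]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        planted = d.get("planted_pair")
        return cls(
            n_respondents=int(d["n_respondents"]),
            marginals=np.asarray(d["marginals"], dtype=float),
            latent_correlation=np.asarray(d["latent_correlation"], dtype=float),
            missing_rate=float(d.get("missing_rate", 0.0)),
            seed=int(d.get("seed", 0)),
            loadings=None if d.get("loadings") is None else np.asarray(d["loadings"], dtype=float),
            planted_pair=None if planted is None else (int(planted[0]), int(planted[1]), float(planted[2])),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def default_config(n_respondents: int = 4025, seed: int = 0) -> SimulationConfig:
    """Config emulating a community screening sample of older adults."""
    return SimulationConfig(
        n_respondents=n_respondents,
        marginals=default_marginals(),
        latent_correlation=one_factor_correlation(default_loadings()),
        seed=seed,
        loadings=default_loadings(),
    )


# ---------------------------------------------------------------------------
# Copula machinery
# ---------------------------------------------------------------------------


def cut_points(marginals: np.ndarray) -> np.ndarray:
    """Latent-normal cut points reproducing the given marginals.

    Returns a (9, 3) array: item ``i`` takes value ``v`` when its latent
    coordinate falls between cuts ``v-1`` and ``v`` (with -inf/+inf at the
    ends).  Degenerate marginals produce infinite cuts, which is fine.
    """
    cum = np.cumsum(marginals[:, :-1], axis=1)
    with np.errstate(divide="ignore"):
        return ndtri(np.clip(cum, 0.0, 1.0))


def marginals_from_cuts(cuts: np.ndarray) -> np.ndarray:
    """Invert :func:`cut_points`: marginal cell probabilities from cut points."""
    cdf = ndtr(cuts)
    padded = np.column_stack([np.zeros(len(cuts)), cdf, np.ones(len(cuts))])
    return np.diff(padded, axis=1)


def _latent_draw(config: SimulationConfig, n: int, seed_tag: int, seed: Optional[int] = None) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, seed_tag])
    )
    try:
        chol = np.linalg.cholesky(config.latent_correlation)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - blocked by __post_init__
        raise SimulationError("latent_correlation is not positive definite") from exc
    return rng.standard_normal((n, N_ITEMS)) @ chol.T


def _discretise(z: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Map latent coordinates to 0-3 responses via per-item cut points."""
    values = np.zeros(z.shape, dtype=np.int64)
    for i in range(N_ITEMS):
        values[:, i] = np.searchsorted(cuts[i], z[:, i], side="left")
    return values


def generate_responses(config: SimulationConfig) -> pd.DataFrame:
    """Draw a complete response table from the Gaussian copula.

    Returns a DataFrame with an ``id`` column (1..n) and nullable-integer
    columns ``item1..item9``, every value in {0, 1, 2, 3}; no missing values
    are introduced at this stage.
    """
    z = _latent_draw(config, config.n_respondents, _TAG_GENERATE)
    values = _discretise(z, cut_points(config.marginals))
    table = pd.DataFrame(values, columns=ITEM_COLUMNS).astype("Int64")
    table.insert(0, "id", np.arange(1, config.n_respondents + 1))
    return table


def inject_missing(table: pd.DataFrame, missing_rate: float, seed: int) -> pd.DataFrame:
    """Set each item cell to missing independently with probability ``missing_rate``."""
    if not 0.0 <= missing_rate <= 1.0:
        raise SimulationError(f"missing_rate must be in [0, 1], got {missing_rate}")
    out = table.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_MISSING]))
    mask = rng.random((len(table), N_ITEMS)) < missing_rate
    items = out[ITEM_COLUMNS].to_numpy(dtype=object)
    items[mask] = pd.NA
    out[ITEM_COLUMNS] = pd.DataFrame(items, columns=ITEM_COLUMNS, index=out.index).astype("Int64")
    return out


# ---------------------------------------------------------------------------
# Prevalence calibration
# ---------------------------------------------------------------------------


def estimate_prevalence(config: SimulationConfig, n_mc: int = 100_000) -> float:
    """Monte-Carlo estimate of P(total score >= 10) under the config.

    Uses a fixed internal seed so that the estimate is a deterministic
    function of the config alone.
    """
    z = _latent_draw(config, n_mc, _TAG_CALIBRATE, seed=_CALIBRATION_SEED)
    values = _discretise(z, cut_points(config.marginals))
    return float(np.mean(values.sum(axis=1) >= SCREEN_POSITIVE_CUTOFF))


def calibrate_prevalence(
    config: SimulationConfig,
    target_prevalence: float,
    tolerance: float = 0.02,
    n_mc: int = 100_000,
    max_offset: float = 8.0,
) -> SimulationConfig:
    """Shift all cut points by one scalar severity offset to hit a target prevalence.

    A positive offset lowers every cut point, pushing mass into higher
    response categories and raising the screen-positive rate; the map from
    offset to prevalence is therefore monotone and is solved by bisection on
    a single Monte-Carlo latent sample (common random numbers make the
    empirical prevalence exactly monotone in the offset).
    """
    if not 0.0 < target_prevalence < 1.0:
        raise SimulationError(f"target_prevalence must be in (0, 1), got {target_prevalence}")
    if tolerance <= 0:
        raise SimulationError("tolerance must be positive")

    z = _latent_draw(config, n_mc, _TAG_CALIBRATE, seed=_CALIBRATION_SEED)
    base_cuts = cut_points(config.marginals)

    def prevalence_at(offset: float) -> float:
        values = _discretise(z, base_cuts - offset)
        return float(np.mean(values.sum(axis=1) >= SCREEN_POSITIVE_CUTOFF))

    lo, hi = -max_offset, max_offset
    p_lo, p_hi = prevalence_at(lo), prevalence_at(hi)
    if not p_lo - tolerance <= target_prevalence <= p_hi + tolerance:
        raise SimulationError(
            f"target prevalence {target_prevalence:.3f} unreachable within offset "
            f"bounds ±{max_offset} (achievable range [{p_lo:.4f}, {p_hi:.4f}])"
        )

    offset = 0.0
    for _ in range(200):
        offset = 0.5 * (lo + hi)
        p = prevalence_at(offset)
        if abs(p - target_prevalence) <= tolerance * 0.5:
            break
        if p < target_prevalence:
            lo = offset
        else:
            hi = offset
    else:  # pragma: no cover - bisection on a monotone step function converges
        p = prevalence_at(offset)
        if abs(p - target_prevalence) > tolerance:
            raise SimulationError(
                f"calibration did not converge: best prevalence {p:.4f} "
                f"vs target {target_prevalence:.4f}"
            )

    new_marginals = marginals_from_cuts(base_cuts - offset)
    return dataclasses.replace(config, marginals=new_marginals)


# ---------------------------------------------------------------------------
# Planted informative pair
# ---------------------------------------------------------------------------


def plant_informative_pair(
    config: SimulationConfig, pair: tuple[int, int], boost: float
) -> SimulationConfig:
    """Boost two items' factor loadings so they dominate the latent severity signal.

    The latent correlation is rebuilt from the config's one-factor loadings
    with the planted items' loadings multiplied by ``boost`` and the matrix
    projected back to the nearest valid correlation matrix.  The planted
    items then carry the most information about the common factor that
    drives the sum score, giving a known best pairing.
    """
    i, j = pair
    if i == j or not (1 <= i <= N_ITEMS and 1 <= j <= N_ITEMS):
        raise SimulationError(f"pair must be two distinct item indices in 1..{N_ITEMS}, got {pair}")
    if boost < 1.0:
        raise SimulationError(f"boost must be >= 1, got {boost}")
    if config.loadings is None:
        raise SimulationError(
            "config has no one-factor loadings; plant_informative_pair requires a "
            "loading-based latent correlation (see default_config)"
        )
    lam = config.loadings.copy()
    lam[[i - 1, j - 1]] *= boost
    if np.any(np.abs(lam) >= 1.0):
        raise SimulationError(
            f"boost {boost} pushes a loading to {np.abs(lam).max():.4f} >= 1; "
            "reduce the boost or the base loadings"
        )
    corr = one_factor_correlation(lam)
    min_eig = float(np.linalg.eigvalsh(corr)[0])
    if min_eig <= 0:  # pragma: no cover - one-factor matrices with |lam|<1 are PD
        corr = corr_nearest(corr, threshold=1e-10)
    return dataclasses.replace(
        config,
        latent_correlation=corr,
        loadings=lam,
        planted_pair=(min(i, j), max(i, j), float(boost)),
    )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def write_responses(table: pd.DataFrame, path: str | Path) -> None:
    """Write a response table as CSV; missing cells become empty fields."""
    table.to_csv(path, index=False)
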