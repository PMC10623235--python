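"""Ingestion and preprocessing of raw questionnaire response tables.

The preprocessing contract mirrors common practice for fixed-length ordinal
questionnaires: rows with more than two missing item responses are excluded,
remaining gaps are imputed with the item's modal observed response (ordinal
items have no meaningful mean), the total score is the plain item sum, and
the screen-positive label is total >= 10.

Each data set is preprocessed independently: modes are computed from the
table at hand, never borrowed across samples.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import ITEM_COLUMNS, N_ITEMS, SCREEN_POSITIVE_CUTOFF

MAX_MISSING_ITEMS = 2
VALID_RESPONSES = (0, 1, 2, 3)


class ValidationError(ValueError):
    """A response table violates the input contract (range, shape, or support)."""


def read_responses(
    path: str | Path,
    column_mapping: Optional[dict[str, str]] = None,
    id_column: str = "id",
) -> pd.DataFrame:
    """Read a CSV/TSV response table into the canonical ``id, item1..item9`` form.

    ``column_mapping`` maps canonical names (``item1``..``item9``) to the
    file's column names when they differ.  Missing cells may be empty fields.
    The file extension selects the delimiter (``.tsv`` -> tab).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep)
    mapping = {canonical: canonical for canonical in ITEM_COLUMNS}
    if column_mapping:
        mapping.update(column_mapping)
    missing_cols = [src for src in mapping.values() if src not in raw.columns]
    if missing_cols:
        raise ValidationError(f"input file lacks required columns: {missing_cols}")
    table = pd.DataFrame()
    if id_column in raw.columns:
        table["id"] = raw[id_column]
    else:
        table["id"] = np.arange(1, len(raw) + 1)
    for canonical, src in mapping.items():
        col = pd.to_numeric(raw[src], errors="coerce")
        # preserve genuinely non-numeric entries as validation failures later
        bad_text = raw[src].notna() & col.isna()
        if bad_text.any():
            row = raw.index[bad_text][0]
            raise ValidationError(
                f"column {src!r} contains non-numeric value {raw[src][row]!r} "
                f"at row {row}"
            )
        if (col.dropna() % 1 != 0).any():
            raise ValidationError(f"column {src!r} contains non-integer responses")
        table[canonical] = col.astype("Int64")
    return table


def validate_and_filter(raw: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Validate response values and drop rows with more than two missing items.

    Returns ``(filtered, n_excluded)`` with row order preserved.  Any
    observed value outside {0, 1, 2, 3} is a row-level validation error
    naming the respondent and the offending value — never a silent coercion.
    """
    _check_columns(raw)
    items = raw[ITEM_COLUMNS]
    values = items.to_numpy(dtype="float64", na_value=np.nan)
    observed = ~np.isnan(values)
    out_of_range = observed & ~np.isin(values, VALID_RESPONSES)
    if out_of_range.any():
        r, c = np.argwhere(out_of_range)[0]
        rid = raw["id"].iloc[r] if "id" in raw.columns else raw.index[r]
        raise ValidationError(
            f"respondent {rid}: {ITEM_COLUMNS[c]} has value {values[r, c]:g}, "
            f"outside the 0-3 response range"
        )
    n_missing = (~observed).sum(axis=1)
    keep = n_missing <= MAX_MISSING_ITEMS
    filtered = raw.loc[keep].copy()
    return filtered, int((~keep).sum())


def impute_mode(filtered: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells with the item's most frequent observed response.

    Ties are broken toward the lower (less symptomatic) response value.
    Requires every row to have at most two missing items and every item
    column to have at least one observed value.
    """
    _check_columns(filtered)
    items = filtered[ITEM_COLUMNS]
    n_missing = items.isna().sum(axis=1)
    if (n_missing > MAX_MISSING_ITEMS).any():
        raise ValidationError(
            f"impute_mode requires rows with at most {MAX_MISSING_ITEMS} missing "
            "items; run validate_and_filter first"
        )
    out = filtered.copy()
    for col in ITEM_COLUMNS:
        series = out[col]
        if not series.isna().any():
            continue
        observed = series.dropna()
        if observed.empty:
            raise ValidationError(f"column {col!r} has no observed values; mode undefined")
        counts = observed.value_counts()
        mode = int(min(counts.index[counts == counts.max()]))
        out[col] = series.fillna(mode)
    return out


def score_and_label(complete: pd.DataFrame) -> pd.DataFrame:
    """Attach total score (0-27) and the screen-positive label (total >= 10)."""
    _check_columns(complete)
    items = complete[ITEM_COLUMNS]
    if items.isna().any().any():
        raise ValidationError("score_and_label requires a complete table (no missing values)")
    out = complete.copy()
    out["total"] = items.sum(axis=1).astype(int)
    out["label"] = out["total"] >= SCREEN_POSITIVE_CUTOFF
    return out


def preprocess(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: filter, impute, score, label; plus a JSON-able report."""
    imputed_per_item = {}
    filtered, n_excluded = validate_and_filter(raw)
    for col in ITEM_COLUMNS:
        imputed_per_item[col] = int(filtered[col].isna().sum())
    labeled = score_and_label(impute_mode(filtered))
    report = {
        "rows_read": int(len(raw)),
        "rows_excluded": n_excluded,
        "rows_retained": int(len(labeled)),
        "cells_imputed_per_item": imputed_per_item,
        "cells_imputed_total": int(sum(imputed_per_item.values())),
        "prevalence": float(labeled["label"].mean()) if len(labeled) else float("nan"),
    }
    return labeled, report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def _check_columns(table: pd.DataFrame) -> None:
    missing = [c for c in ITEM_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"table lacks item columns: {missing}")
    if len(ITEM_COLUMNS) != N_ITEMS:  # pragma: no cover - structural constant
        raise AssertionError
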