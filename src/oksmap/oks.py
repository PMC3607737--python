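"""Oxford Knee Score (OKS) validation, scoring and design encoding.

The OKS is a 12-item knee-replacement outcome questionnaire.  Each item is
scored 4 (no problems) down to 0 (severe problems); the unweighted sum gives
a total from 0 (worst) to 48 (best).

The mapping models use three explanatory codings of a questionnaire:

``dummies48``
    48 indicator variables — one per item per level 0..3, with level 4 (no
    problems) as the reference category.  Canonical order: items in the order
    of :data:`ITEMS`, levels 0,1,2,3 within each item.
``scores12``
    the 12 raw item scores (0..4) treated as numeric.
``total1``
    the single total score (0..48).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ITEMS",
    "ITEM_COLUMNS",
    "DUMMY_COLUMNS",
    "OKSResponse",
    "total_score",
    "dummy_encode",
    "decode_dummies",
    "dummy_design",
    "design_matrix",
    "complete_case_filter",
]

#: Canonical item order (the row order of the published coefficient table).
ITEMS = (
    "pain",         # usual level of pain
    "washing",      # trouble with washing and drying
    "transport",    # trouble with transport
    "walking",      # walking time before severe pain
    "standing",     # pain on standing up from sitting
    "limping",      # limping
    "kneeling",     # difficulty kneeling
    "night_pain",   # pain at night
    "work",         # pain interferes with work
    "instability",  # sense of knee instability
    "shopping",     # can do household shopping alone
    "stairs",       # trouble walking down stairs
)

#: Cohort CSV column for each item.
ITEM_COLUMNS = tuple(f"oks_{item}" for item in ITEMS)

#: The 48 dummy names in canonical order (item-major, levels 0..3 within item).
DUMMY_COLUMNS = tuple(f"{item}_{lvl}" for item in ITEMS for lvl in range(4))


@dataclass(frozen=True)
class OKSResponse:
    """A complete OKS questionnaire: 12 item scores, each in {0,...,4}."""

    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.scores) != 12:
            raise ValueError(f"OKS has 12 items; got {len(self.scores)}")
        for item, score in zip(ITEMS, self.scores):
            if score not in (0, 1, 2, 3, 4):
                raise ValueError(
                    f"OKS item {item!r} must be scored 0-4; got {score!r}"
                )

    @classmethod
    def from_mapping(cls, values) -> "OKSResponse":
        """Build from a mapping keyed by item name or cohort column name."""
        scores = []
        for item, column in zip(ITEMS, ITEM_COLUMNS):
            if item in values:
                scores.append(int(values[item]))
            elif column in values:
                scores.append(int(values[column]))
            else:
                raise KeyError(f"missing OKS item {item!r}")
        return cls(tuple(scores))

    @property
    def total(self) -> int:
        return sum(self.scores)


def total_score(resp: OKSResponse) -> int:
    """Unweighted sum of the 12 item scores (0 worst .. 48 best)."""
    return resp.total


def dummy_encode(resp: OKSResponse) -> np.ndarray:
    """48-vector of level indicators; level 4 is the all-zero reference."""
    out = np.zeros(48)
    for i, score in enumerate(resp.scores):
        if score < 4:
            out[4 * i + score] = 1.0
    return out


def decode_dummies(vector) -> OKSResponse:
    """Inverse of :func:`dummy_encode`."""
    vector = np.asarray(vector)
    if vector.shape != (48,):
        raise ValueError(f"expected a 48-vector, got shape {vector.shape}")
    scores = []
    for i in range(12):
        block = vector[4 * i : 4 * i + 4]
        hits = np.flatnonzero(block == 1)
        if len(hits) > 1 or not set(np.unique(block)) <= {0.0, 1.0}:
            raise ValueError(f"invalid dummy block for item {ITEMS[i]!r}: {block}")
        scores.append(int(hits[0]) if len(hits) else 4)
    return OKSResponse(tuple(scores))


def _item_frame(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ITEM_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"cohort table missing OKS columns: {missing}")
    items = data[list(ITEM_COLUMNS)]
    bad = ~(items.isin([0, 1, 2, 3, 4]) | items.isna())
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.loc[row].idxmax()
        raise ValueError(
            f"invalid OKS value {items.loc[row, col]!r} at row {row}, "
            f"column {col!r} (scores must be 0-4)"
        )
    return items


def dummy_design(data: pd.DataFrame) -> pd.DataFrame:
    """48-column indicator design for a cohort table (canonical order)."""
    items = _item_frame(data)
    if items.isna().any().any():
        raise ValueError("cohort has missing OKS items; run complete_case_filter")
    blocks = {}
    for item, column in zip(ITEMS, ITEM_COLUMNS):
        for lvl in range(4):
            blocks[f"{item}_{lvl}"] = (items[column] == lvl).astype(float)
    return pd.DataFrame(blocks, index=data.index)[list(DUMMY_COLUMNS)]


def design_matrix(
    data: pd.DataFrame, coding: str = "dummies48", merge_map: dict | None = None
) -> pd.DataFrame:
    """Explanatory design under one of the three codings.

    ``merge_map`` (dummies48 only) maps an item name to a list of levels to
    collapse into a single indicator, e.g. ``{"washing": [0, 1]}`` — used to
    resolve perfect separation in the logistic parts of the composite models.
    """
    if coding == "dummies48":
        design = dummy_design(data)
        for item, levels in (merge_map or {}).items():
            if item not in ITEMS:
                raise ValueError(f"unknown OKS item in merge_map: {item!r}")
            levels = sorted(int(v) for v in levels)
            if len(levels) < 2 or any(v not in range(4) for v in levels):
                raise ValueError(f"merge_map[{item!r}] must list >=2 levels in 0-3")
            cols = [f"{item}_{v}" for v in levels]
            merged = design[cols].sum(axis=1)
            design = design.drop(columns=cols)
            design[f"{item}_{'_'.join(str(v) for v in levels)}"] = merged
        return design
    if merge_map:
        raise ValueError("merge_map applies only to the dummies48 coding")
    if coding == "scores12":
        return _item_frame(data).astype(float).rename(
            columns=dict(zip(ITEM_COLUMNS, ITEMS))
        )
    if coding == "total1":
        items = _item_frame(data)
        return pd.DataFrame({"total_oks": items.sum(axis=1)}, index=data.index)
    raise ValueError(f"unknown coding {coding!r}")


def complete_case_filter(
    data: pd.DataFrame, require_eq5d: bool = False
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep only questionnaires with complete OKS (and, optionally, EQ-5D).

    Returns the retained rows and an exclusion report counting dropped
    records by reason (``missing_oks``, ``missing_eq5d``).  No imputation is
    attempted: partially answered questionnaires are excluded outright.
    """
    from .tariff import EQ5D_COLUMNS

    items = _item_frame(data)
    missing_oks = items.isna().any(axis=1)
    report: dict[str, int] = {}
    drop = missing_oks
    if require_eq5d:
        eq_missing = [c for c in EQ5D_COLUMNS if c not in data.columns]
        if eq_missing:
            raise ValueError(f"cohort table missing EQ-5D columns: {eq_missing}")
        missing_eq = data[list(EQ5D_COLUMNS)].isna().any(axis=1)
        n_eq = int((missing_eq & ~missing_oks).sum())
        if n_eq:
            report["missing_eq5d"] = n_eq
        drop = drop | missing_eq
    n_oks = int(missing_oks.sum())
    if n_oks:
        report["missing_oks"] = n_oks
    return data.loc[~drop].copy(), report
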