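"""Descriptive statistics and multi-authority guideline compliance.

Produces the per-parameter summary (range, mean ± sample SD) and the
exceedance accounting against the WHO / US EPA / BDWS registry: per-sample
binary flags, per-(authority, parameter) counts and percentages.

One deliberate fidelity choice: the source accounting reports zero pH
exceedances even though the observed pH minimum (6.12) lies below the
6.5-8.5 acceptable range.  By default pH therefore never flags; pass
``strict_ph=True`` to apply the range rule literally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import math

import pandas as pd

from .core_data import Dataset, GuidelineRule, WaterSample

__all__ = [
    "ComplianceCell",
    "round_half_up",
    "descriptive_stats",
    "exceedance_flags",
    "compliance_table",
]

#: Dataset column per guideline parameter.
_PARAM_COLUMN = {"ph": "ph", "ec": "ec", "tds": "tds", "fe": "fe", "as": "as"}


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    x = float(x)
    if math.isnan(x) or math.isinf(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComplianceCell:
    """Exceedance count for one (authority, parameter) rule."""

    authority: str
    parameter: str
    n_exceeding: int
    pct_exceeding: float     # % of non-missing samples, 1 decimal, half-up
    rule: GuidelineRule


def descriptive_stats(dataset: Dataset) -> pd.DataFrame:
    """Per-parameter min / max / mean / sd (sample, n-1 denominator).

    sd is NaN when fewer than two observations are available for a column.
    """
    if len(dataset) == 0:
        raise ValueError("descriptive_stats needs a non-empty dataset")
    params = ["depth", "ph", "ec", "tds", "temperature", "salinity", "fe", "as"]
    df = dataset.df[params]
    return pd.DataFrame({
        "min": df.min(),
        "max": df.max(),
        "mean": df.mean(),
        "sd": df.std(ddof=1),
    })


def exceedance_flags(
    sample: WaterSample,
    registry: Sequence[GuidelineRule],
    *,
    strict_ph: bool = False,
) -> dict[tuple[str, str], float]:
    """Binary exceedance flag per (authority, parameter); NaN for missing values."""
    flags: dict[tuple[str, str], float] = {}
    for rule in registry:
        if rule.parameter not in _PARAM_COLUMN:
            raise ValueError(f"unknown parameter {rule.parameter!r}")
        value = sample.as_conc if rule.parameter == "as" else getattr(sample, rule.parameter)
        if isinstance(value, float) and math.isnan(value):
            flags[(rule.authority, rule.parameter)] = float("nan")
            continue
        if rule.parameter == "ph" and not strict_ph:
            flags[(rule.authority, rule.parameter)] = 0.0
            continue
        flags[(rule.authority, rule.parameter)] = float(rule.exceeded_by(value))
    return flags


def compliance_table(
    dataset: Dataset,
    registry: Sequence[GuidelineRule],
    *,
    strict_ph: bool = False,
) -> list[ComplianceCell]:
    """One cell per rule; counts are sums of per-sample exceedance flags."""
    if len(dataset) == 0:
        raise ValueError("compliance_table needs n >= 1")
    df = dataset.df
    cells: list[ComplianceCell] = []
    for rule in registry:
        col = _PARAM_COLUMN.get(rule.parameter)
        if col is None:
            raise ValueError(f"unknown parameter {rule.parameter!r}")
        values = df[col].dropna()
        if rule.parameter == "ph" and not strict_ph:
            n_exc = 0
        else:
            n_exc = int(values.map(rule.exceeded_by).sum())
        n = len(values)
        pct = round_half_up(100.0 * n_exc / n, 1) if n else float("nan")
        cells.append(ComplianceCell(rule.authority, rule.parameter, n_exc, pct, rule))
    return cells


def compliance_frame(cells: Sequence[ComplianceCell]) -> pd.DataFrame:
    """Tabular view of a compliance table for reporting."""
    return pd.DataFrame([
        {
            "parameter": c.parameter,
            "authority": c.authority,
            "lower": c.rule.lower,
            "upper": c.rule.upper,
            "exceed_mode": c.rule.exceed_mode,
            "n_exceeding": c.n_exceeding,
            "pct_exceeding": c.pct_exceeding,
        }
        for c in cells
    ])
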