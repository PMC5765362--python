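"""Small linear-model checks: gene copy number vs a quantitative trait
(e.g. spermatid diameter), and expression vs genomic cluster or protein
subfamily.

Both fits are closed-form ordinary least squares; F-tail probabilities come
from the F distribution (regularised incomplete beta), so any standard
implementation agrees to ~1e-10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LinearModelResult:
    formula: str
    coefficients: dict[str, float]
    F: float
    df1: int
    df2: int
    p_value: float
    group_means: dict[str, tuple[float, float]] | None = None  # mean, SE

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "formula": self.formula,
            "coefficients": self.coefficients,
            "F": None if np.isinf(self.F) else self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "group_means": self.group_means,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    expression: float  # FPKM
    cluster_id: str
    subfamily_id: str

    def __post_init__(self) -> None:
        if self.expression < 0:
            raise ValueError(f"{self.gene_id}: negative expression")


def ols_regression(x: Sequence[float], y: Sequence[float]) -> LinearModelResult:
    """Simple linear regression y ~ x with the overall F test (df 1, n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("x is constant")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    fitted = intercept + slope * x
    ss_reg = np.sum((fitted - y.mean()) ** 2)
    ss_res = np.sum((y - fitted) ** 2)
    df1, df2 = 1, n - 2
    if ss_res == 0.0:
        f = np.inf if ss_reg > 0 else 0.0
    else:
        f = (ss_reg / df1) / (ss_res / df2)
    p = 1.0 if f == 0.0 else float(stats.f.sf(f, df1, df2))
    return LinearModelResult(
        formula="y ~ x",
        coefficients={"intercept": float(intercept), "slope": float(slope)},
        F=float(f),
        df1=df1,
        df2=df2,
        p_value=p,
    )


def oneway_anova(values: Sequence[float], groups: Sequence[str]) -> LinearModelResult:
    """One-way ANOVA with F on (k-1, n-k) df and per-group means +/- SE
    (SE = sqrt(MSE / n_g), from the pooled residual variance)."""
    y = np.asarray(values, dtype=float)
    g = np.asarray([str(x) for x in groups])
    if y.size != g.size:
        raise ValueError("values and groups must have equal length")
    levels = sorted(set(g))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    n = y.size
    k = len(levels)
    if n - k < 1:
        raise ValueError("zero within-group degrees of freedom")
    grand = y.mean()
    ss_between = ss_within = 0.0
    means = {}
    for lv in levels:
        yi = y[g == lv]
        ss_between += yi.size * (yi.mean() - grand) ** 2
        ss_within += np.sum((yi - yi.mean()) ** 2)
        means[lv] = yi
    df1, df2 = k - 1, n - k
    mse = ss_within / df2
    if mse == 0.0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df1) / mse
    p = 1.0 if f == 0.0 else float(stats.f.sf(f, df1, df2))
    group_means = {
        lv: (float(yi.mean()), float(np.sqrt(mse / yi.size))) for lv, yi in means.items()
    }
    return LinearModelResult(
        formula="y ~ group",
        coefficients={f"mean[{lv}]": float(yi.mean()) for lv, yi in means.items()},
        F=float(f),
        df1=df1,
        df2=df2,
        p_value=p,
        group_means=group_means,
    )


def copy_number_vs_trait(trait_table: pd.DataFrame) -> LinearModelResult:
    """Linear model of gene copy number on a per-species trait.

    ``trait_table`` needs columns ``copy_number`` and ``trait`` (one row per
    species).
    """
    return ols_regression(trait_table["trait"], trait_table["copy_number"])


def expression_model(
    records: Sequence[ExpressionRecord], by: str = "cluster"
) -> LinearModelResult:
    """ANOVA of expression on cluster_id (``by='cluster'``) or subfamily_id
    (``by='subfamily'``)."""
    if by not in ("cluster", "subfamily"):
        raise ValueError("by must be 'cluster' or 'subfamily'")
    values = [r.expression for r in records]
    groups = [r.cluster_id if by == "cluster" else r.subfamily_id for r in records]
    return oneway_anova(values, groups)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ExpressionRecord(
            str(r.gene_id), float(r.expression), str(r.cluster_id), str(r.subfamily_id)
        )
        for r in df.itertuples()
    ]
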