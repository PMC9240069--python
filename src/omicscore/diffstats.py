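"""Per-feature differential statistics.

Metabolite (or lipid) levels are compared between groups with Welch's
unequal-variance two-sample t-test or classical one-way ANOVA; fold changes
are reported as log2 ratios of group means; raw p-values are adjusted with
the Benjamini–Hochberg step-up procedure.  Lipid intensity matrices are
brought to a common scale by log2 transform followed by per-feature
median/IQR normalization.

All tests use available cases: a feature needs at least ``min_per_group``
non-missing values in every compared group, otherwise it is emitted with
missing statistics and excluded from the FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureMatrix

DIRECTIONS = ("up", "down", "null")


def _clean(values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom.

    Returns ``(t, df, p)`` with a two-sided p-value.  Each group must have at
    least two non-missing values.
    """
    a, b = _clean(group_a), _clean(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"welch_t needs ≥2 values per group, got {len(a)} and {len(b)}")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F-test across ≥2 groups of ≥2 values each."""
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 2:
        raise ValueError("one_way_anova needs at least two groups")
    for i, g in enumerate(cleaned):
        if len(g) < 2:
            raise ValueError(f"one_way_anova group {i} has {len(g)} values, need ≥2")
    f, p = stats.f_oneway(*cleaned)
    # identical groups give 0/0 in scipy; the F statistic is 0 by convention
    if np.isnan(f) and all(np.allclose(g, cleaned[0], equal_nan=True) for g in cleaned):
        return 0.0, 1.0
    return float(f), float(p)


def log2_fold_change(
    group_a: Sequence[float], group_b: Sequence[float], scale: str = "raw"
) -> float:
    """log2 fold change of A over B.

    ``scale='raw'``: log2(mean(A)/mean(B)), requiring positive means.
    ``scale='log2'``: mean(A) − mean(B) (means of already-log2 values).
    """
    a, b = _clean(group_a), _clean(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("log2_fold_change needs non-empty groups")
    if scale == "raw":
        ma, mb = a.mean(), b.mean()
        if ma <= 0 or mb <= 0:
            raise ValueError(f"non-positive group mean on raw scale: {ma}, {mb}")
        return float(np.log2(ma / mb))
    if scale == "log2":
        return float(a.mean() - b.mean())
    raise ValueError(f"unknown scale {scale!r}")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_iqr_normalize(matrix: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """log2 transform then per-feature median-center and IQR-scale.

    Raw positive intensities are log2 transformed, then each feature is
    centered by its median and scaled by its interquartile range across
    samples.  Features with zero IQR are centered only and returned in the
    flag list.  Output unit is ``log2``.
    """
    if matrix.unit != "raw":
        raise ValueError("median_iqr_normalize expects raw intensities")
    vals = matrix.values
    if (vals <= 0).any().any():
        bad = vals.columns[(vals <= 0).any(axis=0)][0]
        raise ValueError(f"non-positive intensity in feature {bad!r}")
    logged = np.log2(vals)
    med = logged.median(axis=0)
    q75 = logged.quantile(0.75, axis=0)
    q25 = logged.quantile(0.25, axis=0)
    iqr = q75 - q25
    zero_iqr = list(iqr.index[iqr == 0])
    scale = iqr.replace(0, 1.0)
    out = (logged - med) / scale
    return FeatureMatrix(out, sample_metadata=matrix.sample_metadata.copy(), unit="log2"), zero_iqr


@dataclass
class ComparisonDesign:
    """Which groups to compare and how.

    ``group_a`` vs ``group_b`` (reference) define the log2FC contrast and,
    for Welch, the tested pair.  For ANOVA the p-value comes from the F-test
    across *all* levels of ``group_column`` while the fold change still uses
    the named contrast.
    """

    group_a: str
    group_b: str
    group_column: str = "group"


def differential_table(
    matrix: FeatureMatrix,
    design: ComparisonDesign,
    method: str = "welch",
    alpha: float = 0.05,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-feature differential statistics for one comparison.

    Returns a DataFrame indexed by feature with columns ``log2FC``,
    ``statistic``, ``p``, ``fdr``, ``direction`` (up/down/null), ``n_a``,
    ``n_b`` and ``tested``.  Raw matrices are log2 transformed first, so
    fold changes are differences of log2 group means.  Features with fewer
    than ``min_per_group`` observations in a compared group keep their row
    but carry missing statistics and do not enter the BH adjustment.
    Direction is ``up``/``down`` only when raw p ≤ alpha.
    """
    if method not in ("welch", "anova"):
        raise ValueError(f"unknown method {method!r}")
    groups = matrix.groups(design.group_column)
    levels = list(pd.unique(groups.dropna()))
    for label in (design.group_a, design.group_b):
        if label not in levels:
            raise ValueError(f"unknown group label {label!r}; available: {levels}")

    vals = matrix.values
    if matrix.unit == "raw":
        if (vals <= 0).any().any():
            raise ValueError("raw matrix has non-positive intensities; cannot log2")
        vals = np.log2(vals)

    mask_a = (groups == design.group_a).to_numpy()
    mask_b = (groups == design.group_b).to_numpy()
    level_masks = {lv: (groups == lv).to_numpy() for lv in levels}

    records = []
    for feat in vals.columns:
        col = vals[feat].to_numpy()
        a = col[mask_a]
        b = col[mask_b]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        rec = {"feature_id": feat, "n_a": len(a), "n_b": len(b)}
        enough = len(a) >= min_per_group and len(b) >= min_per_group
        if method == "anova":
            per_level = [col[m][~np.isnan(col[m])] for m in level_masks.values()]
            enough = enough and all(len(g) >= min_per_group for g in per_level)
        if not enough:
            rec.update(log2FC=np.nan, statistic=np.nan, p=np.nan, tested=False)
        else:
            lfc = float(a.mean() - b.mean())
            if method == "welch":
                t, _df, p = welch_t(a, b)
                rec.update(log2FC=lfc, statistic=t, p=p, tested=True)
            else:
                f, p = one_way_anova(per_level)
                rec.update(log2FC=lfc, statistic=f, p=p, tested=True)
        records.append(rec)

    table = pd.DataFrame.from_records(records).set_index("feature_id")
    table["fdr"] = np.nan
    tested = table.index[table.tested]
    if len(tested):
        table.loc[tested, "fdr"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    sig = table.tested & (table.p <= alpha)
    table["direction"] = "null"
    table.loc[sig & (table.log2FC > 0), "direction"] = "up"
    table.loc[sig & (table.log2FC < 0), "direction"] = "down"
    table.attrs["alpha"] = alpha
    table.attrs["comparison"] = f"{design.group_a}_vs_{design.group_b}"
    table.attrs["method"] = method
    return table
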