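"""Expression-signature activity scoring and survival stratification.

The activity score of a transcriptional signature (e.g. a MYCN-activity
signature of genes that move upon MYCN depletion) is computed per patient as
the sum of per-gene Z-scores of the upregulated genes minus the sum over the
downregulated genes.  Cohorts are stratified into expression tertiles and the
top vs bottom tertile compared with the Kaplan–Meier / log-rank machinery;
ranking −log10(p) across a transporter gene set surfaces genes whose
expression predicts outcome, colored by which tertile fares worse.  CRISPR
gene-effect (dependency) scores are aggregated per disease, lower = more
dependent.

The two-group log-rank statistic is computed in-package from the standard
observed − expected decomposition over event times (with hypergeometric
variance), which also yields the direction of the effect; Kaplan–Meier
product-limit curves come from lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io import FeatureMatrix, SurvivalTable

import logging

logger = logging.getLogger("omicscore")


def zscore_genes(expression: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Standardize every gene to mean 0, sample SD 1 across samples.

    Genes with zero variance are emitted as all-zero and returned in the
    flag list.  Requires ≥2 samples.
    """
    vals = expression.values
    if len(vals) < 2:
        raise ValueError("Z-scoring needs ≥2 samples")
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    flat = list(sd.index[sd == 0])
    safe_sd = sd.replace(0, 1.0)
    z = (vals - mean) / safe_sd
    z[flat] = 0.0
    return FeatureMatrix(z, sample_metadata=expression.sample_metadata.copy(), unit="log2"), flat


@dataclass
class SignatureScore:
    """Per-sample signature activity (Σ Z(up) − Σ Z(down))."""

    scores: pd.Series
    n_up_used: int
    n_down_used: int


def activity_score(
    z: FeatureMatrix, up_genes: list[str], down_genes: list[str]
) -> SignatureScore:
    """Signature activity per sample from a Z-scored expression matrix.

    Genes absent from the matrix are skipped (logged); the up and down lists
    must be disjoint and at least one signature gene must be present.
    """
    overlap = set(up_genes) & set(down_genes)
    if overlap:
        raise ValueError(f"up/down gene lists overlap: {sorted(overlap)[:5]}")
    present_up = [g for g in up_genes if g in z.values.columns]
    present_down = [g for g in down_genes if g in z.values.columns]
    missing = (len(up_genes) - len(present_up)) + (len(down_genes) - len(present_down))
    if missing:
        logger.info("%d signature genes absent from the matrix were skipped", missing)
    if not present_up and not present_down:
        raise ValueError("no signature genes present in the expression matrix")
    score = pd.Series(0.0, index=z.values.index)
    if present_up:
        score = score + z.values[present_up].sum(axis=1)
    if present_down:
        score = score - z.values[present_down].sum(axis=1)
    return SignatureScore(score, len(present_up), len(present_down))


def masked_correlations(
    expression: FeatureMatrix,
    targets: list[str],
    extra: SignatureScore | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with entries masked when p ≥ alpha.

    Correlates the target genes (and optionally a signature-score vector,
    labeled ``activity``) pairwise; returns ``(r, mask)`` where ``mask`` is
    True for entries to hide (insignificant or degenerate).  Zero-variance
    vectors are masked and flagged via log.
    """
    if len(expression.values) < 3:
        raise ValueError("correlation needs ≥3 samples")
    cols = {}
    for g in targets:
        if g in expression.values.columns:
            cols[g] = expression.values[g].to_numpy(dtype=float)
        else:
            logger.info("target gene %s absent from matrix, skipped", g)
    if extra is not None:
        cols["activity"] = extra.scores.reindex(expression.values.index).to_numpy(dtype=float)
    names = list(cols)
    k = len(names)
    r = pd.DataFrame(np.eye(k), index=names, columns=names)
    mask = pd.DataFrame(False, index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            x, y = cols[names[i]], cols[names[j]]
            if np.std(x) == 0 or np.std(y) == 0:
                logger.info("zero-variance vector in correlation (%s, %s)", names[i], names[j])
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                mask.iloc[i, j] = mask.iloc[j, i] = True
                continue
            rr, p = stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rr
            if p >= alpha:
                mask.iloc[i, j] = mask.iloc[j, i] = True
    return r, mask


def tertile_stratify(values: pd.Series) -> tuple[pd.Series, bool]:
    """Label each sample bottom/middle/top by empirical tertile.

    Cuts at the 1/3 and 2/3 quantiles; values tied with a boundary go to the
    lower stratum.  Returns ``(labels, degenerate)`` — degenerate is True
    when the two cut points coincide (e.g. all values equal).
    """
    v = pd.Series(values, dtype=float)
    if len(v) < 3:
        raise ValueError("tertile stratification needs ≥3 samples")
    q1, q2 = v.quantile(1 / 3), v.quantile(2 / 3)
    labels = pd.Series("top", index=v.index)
    labels[v <= q2] = "middle"
    labels[v <= q1] = "bottom"
    return labels, bool(q1 == q2)


@dataclass
class KmLogrankResult:
    group_labels: tuple[str, str]
    curves: dict[str, pd.DataFrame]  # per-group KM survival function
    observed_minus_expected: float   # O − E for the first group
    chi_square: float
    p: float


def km_logrank(
    survival: SurvivalTable,
    groups: pd.Series,
    labels: tuple[str, str] | None = None,
    fit_curves: bool = True,
) -> KmLogrankResult:
    """Two-group Kaplan–Meier curves and log-rank test.

    ``groups`` maps subject → group label.  The chi-square is
    (O₁ − E₁)²/V with O, E, V accumulated over distinct event times
    (hypergeometric variance); p is the upper tail of χ²₁.  The sign of
    O₁ − E₁ says whether the first group had more events than expected
    (fares worse).  ``fit_curves=False`` skips the product-limit curves when
    only the test is needed (bulk gene rankings).
    """
    df = survival.table.copy()
    df["group"] = df.subject.map(groups)
    if df.group.isna().any():
        raise ValueError("every subject needs a group label")
    if labels is None:
        uniq = list(pd.unique(df.group))
        if len(uniq) != 2:
            raise ValueError(f"need exactly two groups, got {uniq}")
        labels = (uniq[0], uniq[1])
    g1, g2 = labels
    for g in labels:
        if not (df.group == g).any():
            raise ValueError(f"group {g!r} has no subjects")
    df = df[df.group.isin(labels)]
    if df.event.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")

    t_arr = df.time.to_numpy(dtype=float)
    e_arr = df.event.to_numpy(dtype=int)
    in_g1 = (df.group == g1).to_numpy()
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(t_arr[e_arr == 1]):
        at_risk = t_arr >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_g1).sum())
        if n == 0 or n1 == 0 or n1 == n:
            continue
        dying = (t_arr == t) & (e_arr == 1)
        d = int(dying.sum())
        d1 = int((dying & in_g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(stats.chi2.sf(chi2, df=1))

    curves = {}
    if fit_curves:
        for g in labels:
            sub = df[df.group == g]
            kmf = KaplanMeierFitter()
            kmf.fit(sub.time, event_observed=sub.event, label=str(g))
            curves[g] = kmf.survival_function_
    return KmLogrankResult((g1, g2), curves, float(o_minus_e), float(chi2), float(p))


def geneset_survival_ranking(
    expression: FeatureMatrix,
    survival_tables: dict[str, SurvivalTable],
    gene_set: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene tertile log-rank significance for each survival endpoint.

    For every gene present in the matrix, samples are stratified into
    expression tertiles and the top vs bottom tertile compared by log-rank
    for each endpoint (e.g. OS, EFS).  Output columns per endpoint:
    ``neglog10_p_<ep>`` and ``class_<ep>`` ∈ {red, blue, gray} — red when the
    high-expression tertile fares worse (p < alpha), blue when the low
    tertile fares worse, gray otherwise.
    """
    rows = []
    for gene in gene_set:
        if gene not in expression.values.columns:
            logger.info("gene %s absent from expression matrix, skipped", gene)
            continue
        labels, degenerate = tertile_stratify(expression.values[gene])
        row: dict[str, object] = {"gene": gene}
        for ep, surv in survival_tables.items():
            if degenerate:
                row[f"neglog10_p_{ep}"], row[f"class_{ep}"] = np.nan, "gray"
                continue
            keep = labels[labels.isin(["top", "bottom"])]
            sub = SurvivalTable(surv.table[surv.table.subject.isin(keep.index)].copy())
            res = km_logrank(sub, keep, labels=("top", "bottom"), fit_curves=False)
            row[f"neglog10_p_{ep}"] = -np.log10(max(res.p, np.finfo(float).tiny))
            if res.p < alpha:
                row[f"class_{ep}"] = "red" if res.observed_minus_expected > 0 else "blue"
            else:
                row[f"class_{ep}"] = "gray"
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def dependency_rank(
    gene_effect: pd.DataFrame,
    gene: str,
    disease_column: str = "disease",
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Aggregate a gene's CRISPR dependency scores per disease, ascending.

    ``gene_effect`` has one row per cell line with a disease label column and
    one column per gene.  Lower (more negative) scores mean stronger
    dependency, so the most dependent disease ranks first.  Both mean and
    median aggregates are reported; ``rank`` follows the requested one and a
    flag marks diseases whose rank differs between the two.
    """
    if gene not in gene_effect.columns:
        raise ValueError(f"gene {gene!r} not in gene-effect table")
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be mean or median, got {aggregate!r}")
    grouped = gene_effect.groupby(disease_column)[gene]
    out = pd.DataFrame({"mean": grouped.mean(), "median": grouped.median(), "n_lines": grouped.size()})
    out = out.sort_values([aggregate, out.index.name or disease_column], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    alt = out["median" if aggregate == "mean" else "mean"].rank(method="first")
    out["rank_differs"] = out["rank"] != alt.astype(int)
    return out
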