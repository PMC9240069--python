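"""Subpathway-level enrichment: DA score, ORA, asterisk ranking, set-permutation
GSEA and the classification network.

The differential abundance (DA) score of a subpathway is

    DA = (#significantly increased − #significantly decreased)
         / #metabolites measured in the subpathway × 100

so +100 means every measured member is significantly up (p ≤ α with positive
log2FC) and −100 means every member is significantly down.  Over-representation
uses the upper-tail hypergeometric test over the measured universe, BH-adjusted
across sets; a set earning adjusted p < 0.25 in a comparison receives an
asterisk, and subpathways are ranked by asterisk count then mean |DA| across
comparisons.

The GSEA variant ranks metabolites by the signal-to-noise metric between two
phenotypes and estimates significance against randomized *metabolite sets*
(same-size random draws from the measured universe), not phenotype
permutations: the enrichment score is the maximum deviation of the weighted
Kolmogorov running sum, the empirical p compares |ES| with same-sign null
scores, and NES divides ES by the mean |same-sign null ES|.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_adjust
from .io import FeatureMatrix, MetaboliteSetCollection, PathwayAnnotation

import logging

logger = logging.getLogger("omicscore")


# ---------------------------------------------------------------------------
# differential abundance score


def _subpathway_counts(diff: pd.DataFrame, members: list[str]) -> tuple[int, int, int]:
    present = [m for m in members if m in diff.index]
    sub = diff.loc[present]
    n_up = int((sub.direction == "up").sum())
    n_down = int((sub.direction == "down").sum())
    return len(present), n_up, n_down


def differential_abundance_score(
    diff: pd.DataFrame | Mapping[str, pd.DataFrame],
    annotation: PathwayAnnotation,
    alpha: float = 0.05,
    min_altered_rule: str = "altered",
    min_members: int = 3,
) -> pd.DataFrame:
    """DA score per subpathway, per comparison.

    ``diff`` is a differential table (or mapping comparison → table) whose
    ``direction`` column already encodes significance at ``alpha``.  The
    inclusion rule decides which subpathways are scored:

    - ``"altered"`` (default): at least ``min_members`` significantly altered
      metabolites (p ≤ α, either direction) in at least one comparison;
    - ``"measured"``: at least ``min_members`` measured metabolites.

    Returns a table with one row per (sub_pathway, comparison) and columns
    ``n_measured``, ``n_up``, ``n_down``, ``da_score``, ``included`` and
    ``exclusion_reason``.  Features absent from the annotation are excluded
    and logged.
    """
    if len(annotation.table) == 0:
        raise ValueError("empty pathway annotation")
    if min_altered_rule not in ("altered", "measured"):
        raise ValueError(f"unknown inclusion rule {min_altered_rule!r}")
    tables = diff if isinstance(diff, Mapping) else {"comparison": diff}

    for name, table in tables.items():
        unannotated = [f for f in table.index if f not in annotation.table.index]
        if unannotated:
            logger.info(
                "%d features in %s lack a pathway annotation and are excluded", len(unannotated), name
            )

    rows = []
    for sub in annotation.sub_pathways:
        members = annotation.members(sub)
        per_comp = {name: _subpathway_counts(table, members) for name, table in tables.items()}
        if min_altered_rule == "altered":
            ok = any(n_up + n_down >= min_members for _, n_up, n_down in per_comp.values())
            reason = None if ok else f"<{min_members} altered metabolites in every comparison"
        else:
            ok = any(n_meas >= min_members for n_meas, _, _ in per_comp.values())
            reason = None if ok else f"<{min_members} measured metabolites"
        for name, (n_meas, n_up, n_down) in per_comp.items():
            score = np.nan if n_meas == 0 else (n_up - n_down) / n_meas * 100.0
            rows.append(
                {
                    "sub_pathway": sub,
                    "comparison": name,
                    "n_measured": n_meas,
                    "n_up": n_up,
                    "n_down": n_down,
                    "da_score": score,
                    "included": ok,
                    "exclusion_reason": reason,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["rule"] = min_altered_rule
    return out


# ---------------------------------------------------------------------------
# over-representation (hypergeometric)


def ora_hypergeometric(
    diff: pd.DataFrame,
    sets: MetaboliteSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per set, BH across sets.

    Universe N = features with a computed p-value; K = significant features
    (p ≤ α); per set, n = members inside the universe (outside members are
    dropped with a log note) and k = significant members.  p = P(X ≥ k).
    """
    tested = diff[diff.get("tested", pd.Series(True, index=diff.index)).astype(bool)]
    universe = set(tested.index)
    if not universe:
        raise ValueError("empty measured universe")
    significant = set(tested.index[tested.p <= alpha])
    N, K = len(universe), len(significant)

    rows = []
    for name, members in sets:
        inside = [m for m in members if m in universe]
        dropped = len(members) - len(inside)
        if dropped:
            logger.info("set %s: %d members outside the measured universe dropped", name, dropped)
        n = len(inside)
        k = sum(1 for m in inside if m in significant)
        if n == 0:
            p = np.nan
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    valid = out.index[out.p.notna()]
    out["fdr"] = np.nan
    if len(valid):
        out.loc[valid, "fdr"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# asterisk ranking across comparisons


def rank_subpathways(
    da_scores: pd.DataFrame,
    ora_results: Mapping[str, pd.DataFrame],
    fdr_star_threshold: float = 0.25,
) -> pd.DataFrame:
    """Rank subpathways by asterisk count, then mean |DA score|.

    A subpathway earns one asterisk per comparison in which its ORA adjusted
    p-value falls below ``fdr_star_threshold``.  Ties on asterisk count are
    broken by the average absolute DA score across comparisons (missing
    scores excluded from the average); residual ties alphabetically.
    """
    subs = list(pd.unique(da_scores.sub_pathway))
    rows = []
    for sub in subs:
        stars = 0
        for comp, ora in ora_results.items():
            if sub in ora.index and pd.notna(ora.loc[sub, "fdr"]) and ora.loc[sub, "fdr"] < fdr_star_threshold:
                stars += 1
        da_sub = da_scores[(da_scores.sub_pathway == sub) & da_scores.da_score.notna()]
        mean_abs = float(da_sub.da_score.abs().mean()) if len(da_sub) else 0.0
        rows.append({"sub_pathway": sub, "stars": stars, "mean_abs_da": mean_abs})
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["stars", "mean_abs_da", "sub_pathway"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# signal-to-noise ranking


def signal_to_noise_ranking(
    matrix: FeatureMatrix,
    phenotype: pd.Series | Sequence[str],
    positive_label: str | None = None,
    sigma_floor_fraction: float = 0.2,
) -> pd.DataFrame:
    """Rank features by (μ₁ − μ₂)/(σ₁ + σ₂) between two phenotypes.

    Each group standard deviation is floored at
    ``max(sigma_floor_fraction·|μ|, 1e-8)``.  The returned table is sorted by
    metric descending, ties broken by feature id, and covers the whole
    feature universe.
    """
    labels = pd.Series(phenotype)
    if len(labels) != len(matrix.values):
        raise ValueError("phenotype length must match sample count")
    levels = list(pd.unique(labels.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two phenotype labels, got {levels}")
    if positive_label is None:
        positive_label = levels[0]
    negative_label = [lv for lv in levels if lv != positive_label][0]

    vals = matrix.values.to_numpy(dtype=float)
    m1 = labels.to_numpy() == positive_label
    m2 = labels.to_numpy() == negative_label
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("need ≥2 samples per phenotype")

    mu1, mu2 = vals[m1].mean(axis=0), vals[m2].mean(axis=0)
    sd1 = vals[m1].std(axis=0, ddof=1)
    sd2 = vals[m2].std(axis=0, ddof=1)
    sd1 = np.maximum(sd1, np.maximum(sigma_floor_fraction * np.abs(mu1), 1e-8))
    sd2 = np.maximum(sd2, np.maximum(sigma_floor_fraction * np.abs(mu2), 1e-8))
    metric = (mu1 - mu2) / (sd1 + sd2)

    out = pd.DataFrame({"feature_id": matrix.feature_ids, "metric": metric})
    out = out.sort_values(["metric", "feature_id"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# GSEA with randomized metabolite sets


def _enrichment_score(hit_pos: np.ndarray, weights: np.ndarray, n_total: int) -> float:
    """Max-deviation weighted Kolmogorov running-sum ES.

    ``hit_pos``: sorted 0-based positions of set members in the ranked list;
    ``weights``: |metric|^w at every position.  Hits increment by their
    weight share, misses decrement by 1/(N−n); the ES is the running-sum
    value of largest magnitude (peak at a hit or trough just before one).
    """
    n = len(hit_pos)
    wr = weights[hit_pos]
    total = wr.sum()
    if total <= 0:  # all-zero weights: fall back to unweighted hits
        wr = np.ones(n)
        total = float(n)
    cum_hits = np.cumsum(wr) / total
    miss_step = 1.0 / (n_total - n)
    ranks = np.arange(n)
    misses_before = (hit_pos - ranks) * miss_step  # misses strictly before each hit
    at_hit = cum_hits - misses_before
    before_hit = np.concatenate(([0.0], cum_hits[:-1])) - misses_before
    j_peak = int(np.argmax(at_hit))
    k_trough = int(np.argmin(before_hit))
    peak, trough = at_hit[j_peak], before_hit[k_trough]
    # magnitude ties (within round-off) go to the extreme attained first
    if peak > -trough + 1e-12:
        return float(peak)
    if -trough > peak + 1e-12:
        return float(trough)
    return float(trough) if hit_pos[k_trough] <= hit_pos[j_peak] else float(peak)


def _null_es(
    rng: np.random.Generator, n_perm: int, set_size: int, weights: np.ndarray
) -> np.ndarray:
    """ES of ``n_perm`` random same-size sets drawn from the ranked universe."""
    n_total = len(weights)
    # vectorised sampling without replacement per row
    keys = rng.random((n_perm, n_total))
    pos = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    pos.sort(axis=1)
    wr = weights[pos]
    totals = wr.sum(axis=1)
    degenerate = totals <= 0  # all-zero draws → unweighted
    if degenerate.any():
        wr[degenerate] = 1.0
        totals[degenerate] = set_size
    cum_hits = np.cumsum(wr, axis=1) / totals[:, None]
    miss_step = 1.0 / (n_total - set_size)
    ranks = np.arange(set_size)[None, :]
    misses_before = (pos - ranks) * miss_step
    at_hit = cum_hits - misses_before
    before_hit = np.concatenate([np.zeros((n_perm, 1)), cum_hits[:, :-1]], axis=1) - misses_before
    j_peak = at_hit.argmax(axis=1)
    k_trough = before_hit.argmin(axis=1)
    rows = np.arange(n_perm)
    peak = at_hit[rows, j_peak]
    trough = before_hit[rows, k_trough]
    # on a magnitude tie (within round-off) the extreme attained first wins
    trough_wins = (-trough > peak + 1e-12) | (
        (np.abs(peak + trough) <= 1e-12) & (pos[rows, k_trough] <= pos[rows, j_peak])
    )
    return np.where(trough_wins, trough, peak)


def gsea_enrichment(
    ranked: pd.DataFrame,
    sets: MetaboliteSetCollection,
    n_perm: int = 10000,
    weight: float = 1.0,
    min_set: int = 3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Set-enrichment statistics against randomized metabolite sets.

    ``ranked`` comes from :func:`signal_to_noise_ranking` (columns
    ``feature_id`` and ``metric``, already ordered).  For each set with at
    least ``min_set`` members inside the universe, the weighted running-sum
    ES is computed and compared with ``n_perm`` random same-size sets drawn
    from the universe.  The empirical p uses same-sign null scores with an
    add-one correction; NES = ES / mean|same-sign null ES|; FDR is BH across
    sets.  Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = ranked.feature_id.to_list()
    index_of = {f: i for i, f in enumerate(order)}
    weights = np.abs(ranked.metric.to_numpy(dtype=float)) ** weight
    n_total = len(order)

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in sets:
        inside = sorted({m for m in members if m in index_of})
        if len(inside) < min_set:
            rows.append(
                {"set": name, "size": len(inside), "es": np.nan, "nes": np.nan,
                 "p_perm": np.nan, "skipped": f"<{min_set} members in universe"}
            )
            continue
        if len(inside) >= n_total:
            rows.append(
                {"set": name, "size": len(inside), "es": np.nan, "nes": np.nan,
                 "p_perm": np.nan, "skipped": "set covers the whole universe"}
            )
            continue
        hit_pos = np.array(sorted(index_of[m] for m in inside))
        es = _enrichment_score(hit_pos, weights, n_total)
        size = len(inside)
        if size not in null_cache:
            null_cache[size] = _null_es(rng, n_perm, size, weights)
        null = null_cache[size]
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        n_same = len(same_sign)
        p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (n_same + 1)
        nes = es / np.abs(same_sign).mean() if n_same else np.nan
        rows.append({"set": name, "size": size, "es": es, "nes": nes, "p_perm": p, "skipped": None})

    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = np.nan
    valid = out.index[out.p_perm.notna()]
    if len(valid):
        out.loc[valid, "fdr"] = bh_adjust(out.loc[valid, "p_perm"].to_numpy())
    out.attrs["n_perm"] = n_perm
    out.attrs["weight"] = weight
    return out


# ---------------------------------------------------------------------------
# classification network


def build_classification_network(
    diff_tables: Mapping[str, pd.DataFrame],
    annotation: PathwayAnnotation,
    comparison: str,
    alpha: float = 0.05,
) -> nx.DiGraph:
    """Subpathway → metabolite network for one named comparison.

    Each annotated metabolite present in the comparison's differential table
    becomes a target node with ``size`` = |log2FC| and ``direction_class``
    up/down when p ≤ α with the matching sign, else ``ns``; its subpathway is
    the single source node it hangs from.
    """
    if comparison not in diff_tables:
        raise ValueError(f"comparison {comparison!r} not in diff tables: {list(diff_tables)}")
    diff = diff_tables[comparison]
    net = nx.DiGraph()
    for feat in diff.index:
        sub = annotation.subpathway_of(feat)
        if sub is None:
            continue
        row = diff.loc[feat]
        if pd.notna(row.p) and row.p <= alpha and row.log2FC > 0:
            direction = "up"
        elif pd.notna(row.p) and row.p <= alpha and row.log2FC < 0:
            direction = "down"
        else:
            direction = "ns"
        size = float(abs(row.log2FC)) if pd.notna(row.log2FC) else 0.0
        if sub not in net:
            net.add_node(sub, kind="subpathway")
        net.add_node(feat, kind="metabolite", size=size, direction_class=direction)
        net.add_edge(sub, feat, relation="contains")
    return net
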