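"""Synthetic inputs with known ground truth for every analysis stage.

Each generator emulates the statistical structure the corresponding analysis
assumes, with planted effects recorded in a :class:`GroundTruth`, so the
differential, enrichment, lipid, signature/survival and synergy stages all
have recovery tests without any external data:

- metabolomics / lipidomics — log-normal intensities (Gaussian on the log2
  scale) organised into subpathways or lipid classes, with additive log2
  group shifts planted in named subpathways and optional left-censored
  missingness mimicking detection limits;
- expression cohorts — a latent activity variable drives signature up-genes
  positively and down-genes negatively; survival is exponential with hazard
  increasing in the latent activity, with independent censoring, and an
  amplification label marks the top latent tertile (with configurable
  label error);
- dose grids — monotone single-agent inhibition curves plus combination
  cells equal to the Bliss expectation plus a configured excess and noise.

Every generator takes a seed and owns one ``numpy`` Generator per call: the
same seed gives byte-identical output and there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .io import FeatureMatrix, PathwayAnnotation, SurvivalTable

Direction = Literal["up", "down", "null"]


@dataclass
class SimulationConfig:
    """Shared knobs for the metabolomics/lipidomics generators.

    Defaults mirror the scale of the study designs the package targets:
    small per-group sample sizes, tens of subpathways with a handful of
    metabolites each, unit log2 noise, no missingness.
    """

    n_samples_per_group: int = 10
    n_subpathways: int = 20
    metabolites_per_subpathway: int = 5
    planted_effects: dict[str, tuple[Direction, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    missing_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be ≥ 2")
        if self.metabolites_per_subpathway < 3:
            raise ValueError("metabolites_per_subpathway must be ≥ 3")
        if self.n_subpathways < 1:
            raise ValueError("n_subpathways must be ≥ 1")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for sub, (direction, effect) in self.planted_effects.items():
            if direction not in ("up", "down", "null"):
                raise ValueError(f"planted_effects[{sub!r}]: unknown direction {direction!r}")
            if effect < 0:
                raise ValueError(f"planted_effects[{sub!r}]: effect size must be ≥ 0")


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    subpathway_direction: dict[str, Direction] = field(default_factory=dict)
    expected_da_sign: dict[str, int] = field(default_factory=dict)
    planted_features: dict[str, list[str]] = field(default_factory=dict)
    latent: pd.Series | None = None
    interaction_model: str | None = None
    planted_excess: float | None = None


def _subpathway_names(config: SimulationConfig) -> list[str]:
    names = list(config.planted_effects)
    filler = (f"subpathway_{i:02d}" for i in range(1, 10 * config.n_subpathways))
    while len(names) < config.n_subpathways:
        nxt = next(filler)
        if nxt not in names:
            names.append(nxt)
    if len(names) > config.n_subpathways:
        raise ValueError("more planted subpathways than n_subpathways")
    return names


def _planted_matrix(
    config: SimulationConfig,
    feature_names: dict[str, list[str]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Common log2-scale group-shift machinery for both omics generators."""
    n = config.n_samples_per_group
    samples = [f"g1_s{i:02d}" for i in range(n)] + [f"g2_s{i:02d}" for i in range(n)]
    group = ["group1"] * n + ["group2"] * n
    all_features = [f for feats in feature_names.values() for f in feats]

    base = rng.uniform(10, 20, size=len(all_features))  # per-feature log2 baseline
    log2 = rng.normal(0.0, config.noise_sd, size=(2 * n, len(all_features))) + base

    truth = GroundTruth()
    col = 0
    for sub, feats in feature_names.items():
        direction, effect = config.planted_effects.get(sub, ("null", 0.0))
        shift = {"up": effect, "down": -effect, "null": 0.0}[direction]
        log2[n:, col : col + len(feats)] += shift
        truth.subpathway_direction[sub] = direction if effect > 0 else "null"
        truth.expected_da_sign[sub] = int(np.sign(shift)) if effect > 0 else 0
        if direction != "null" and effect > 0:
            truth.planted_features[sub] = list(feats)
        col += len(feats)

    values = pd.DataFrame(np.exp2(log2), index=samples, columns=all_features)
    if config.missing_fraction > 0:
        # left-censor below each feature's missing_fraction quantile
        cutoff = values.quantile(config.missing_fraction, axis=0)
        values = values.where(values.ge(cutoff, axis=1))
    meta = pd.DataFrame({"group": group}, index=samples)
    return values, meta, truth


def simulate_metabolomics(
    config: SimulationConfig,
) -> tuple[FeatureMatrix, PathwayAnnotation, GroundTruth]:
    """Metabolon-style intensity matrix with subpathway structure.

    Two groups of ``n_samples_per_group`` samples; features are log-normal
    with the planted subpathways shifted by the configured log2 effect in
    group 2.  Returns the raw-intensity matrix, a feature→(super-pathway,
    subpathway) annotation and the planted ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subs = _subpathway_names(config)
    feature_names = {
        sub: [f"met_{sub}_{j:02d}" for j in range(config.metabolites_per_subpathway)]
        for sub in subs
    }
    values, meta, truth = _planted_matrix(config, feature_names, rng)
    ann = pd.DataFrame(
        [
            {"feature_id": f, "super_pathway": "lipid" if sub in ("DG", "TG", "PC", "PE") else "other",
             "sub_pathway": sub}
            for sub, feats in feature_names.items()
            for f in feats
        ]
    ).set_index("feature_id")
    return (
        FeatureMatrix(values, sample_metadata=meta, unit="raw"),
        PathwayAnnotation(ann),
        truth,
    )


DEFAULT_CHAIN_POOL: tuple[str, ...] = ("14:0", "16:0", "16:1", "18:0", "18:1", "18:2")


def simulate_lipidomics(
    config: SimulationConfig,
    chain_pool: tuple[str, ...] = DEFAULT_CHAIN_POOL,
    classes: tuple[str, ...] | None = None,
) -> tuple[FeatureMatrix, GroundTruth]:
    """Lipid intensity matrix keyed by parseable lipid names.

    Lipid classes play the role of subpathways: ``n_subpathways`` classes
    (drawn from the planted keys plus a default palette), each with
    ``metabolites_per_subpathway`` species whose chains are drawn from
    ``chain_pool``.  Planted classes are shifted as configured.
    """
    from .lipids import CLASS_ARITY  # avoid cycle at import time

    config.validate()
    rng = np.random.default_rng(config.seed)
    palette = ["TG", "DG", "PC", "PE", "PI", "PS", "PG", "SM", "CE", "PA", "CL", "dhCER",
               "MGDG", "DGDG", "lyso.PC", "lyso.PE", "plasmenyl.PC", "plasmenyl.PE"]
    if classes is None:
        classes = list(config.planted_effects)
        for c in palette:
            if len(classes) >= config.n_subpathways:
                break
            if c not in classes:
                classes.append(c)
        classes = classes[: config.n_subpathways]
    for c in classes:
        if c not in CLASS_ARITY:
            raise ValueError(f"unknown lipid class {c!r}")

    feature_names: dict[str, list[str]] = {}
    for cls in classes:
        arity = CLASS_ARITY[cls]
        n_possible = len(chain_pool) ** arity
        n_species = min(config.metabolites_per_subpathway, n_possible)
        names: list[str] = []
        if n_possible <= 4 * n_species:  # small name space: enumerate then subsample
            import itertools

            combos = ["/".join(c) for c in itertools.product(chain_pool, repeat=arity)]
            picked = rng.choice(len(combos), size=n_species, replace=False)
            names = [f"{cls}({combos[i]})" for i in sorted(picked)]
        else:
            while len(names) < n_species:
                chains = rng.choice(chain_pool, size=arity, replace=True)
                name = f"{cls}({'/'.join(chains)})"
                if name not in names:
                    names.append(name)
        feature_names[cls] = names
    values, meta, truth = _planted_matrix(config, feature_names, rng)
    return FeatureMatrix(values, sample_metadata=meta, unit="raw"), truth


def simulate_expression_cohort(
    n_patients: int,
    up_genes: list[str],
    down_genes: list[str],
    effect: float,
    seed: int,
    n_background_genes: int = 200,
    hazard_coef: float = 0.5,
    base_hazard: float = 0.1,
    censor_rate: float = 0.05,
    mna_label_error: float = 0.05,
) -> tuple[FeatureMatrix, pd.DataFrame, GroundTruth]:
    """Expression cohort driven by a latent activity with linked survival.

    Each patient has latent activity ~ N(0,1).  Up-genes equal
    ``effect·latent + N(0,1)`` (plus a gene baseline), down-genes the
    negated slope, background genes pure noise.  Survival time is
    exponential with hazard ``base_hazard·exp(hazard_coef·latent)``;
    censoring is an independent exponential.  The amplification label marks
    the top latent tertile, with ``mna_label_error`` of labels flipped.
    Returns (expression matrix, clinical table, truth with the latent).
    """
    if not up_genes or not down_genes:
        raise ValueError("up and down gene lists must be non-empty")
    overlap = set(up_genes) & set(down_genes)
    if overlap:
        raise ValueError(f"up/down gene lists overlap: {sorted(overlap)[:5]}")
    if n_patients < 3:
        raise ValueError("need ≥3 patients")
    rng = np.random.default_rng(seed)

    patients = [f"pt{i:04d}" for i in range(n_patients)]
    latent = rng.normal(size=n_patients)
    genes = list(up_genes) + list(down_genes) + [f"bg{i:04d}" for i in range(n_background_genes)]
    slopes = np.concatenate(
        [np.full(len(up_genes), effect), np.full(len(down_genes), -effect), np.zeros(n_background_genes)]
    )
    baselines = rng.normal(8.0, 2.0, size=len(genes))
    expr = latent[:, None] * slopes[None, :] + rng.normal(size=(n_patients, len(genes))) + baselines
    matrix = FeatureMatrix(pd.DataFrame(expr, index=patients, columns=genes), unit="log2")

    hazard = base_hazard * np.exp(hazard_coef * latent)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / censor_rate, size=n_patients)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    cut = np.quantile(latent, 2 / 3)
    mna = latent > cut
    flip = rng.random(n_patients) < mna_label_error
    mna = np.where(flip, ~mna, mna)
    clinical = pd.DataFrame(
        {
            "subject": patients,
            "time": np.maximum(time, 1e-6),
            "event": event,
            "endpoint": "OS",
            "mycn_amplified": mna.astype(bool),
        }
    )
    truth = GroundTruth(latent=pd.Series(latent, index=patients))
    return matrix, clinical, truth


def simulate_dose_grid(
    doses_a: list[float],
    doses_b: list[float],
    model: str = "bliss-independent",
    excess: float = 0.0,
    reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    ec50_a: float | None = None,
    ec50_b: float | None = None,
    hill: float = 1.0,
):
    """Two-drug viability grid with a known interaction model.

    Single-agent inhibition follows a Hill curve i(d) = d^h/(d^h + EC50^h)
    with EC50 defaulting to the largest dose (so single-agent inhibition
    stays ≤ 50% and planted excess is never clipped).  Combination cells
    equal the Bliss expectation plus ``excess`` percentage points
    (``synergistic``), minus it (``antagonistic``), or exactly
    (``bliss-independent``); Gaussian noise (viability percentage points) is
    added everywhere except the untreated cell, which is 100 by
    normalization.  Replicates differ only in noise.
    """
    from .assays import DoseGrid  # avoid cycle at import time

    if model not in ("bliss-independent", "synergistic", "antagonistic"):
        raise ValueError(f"unknown interaction model {model!r}")
    if any(d <= 0 for d in doses_a) or any(d <= 0 for d in doses_b):
        raise ValueError("doses must be positive (dose 0 margins are added automatically)")
    if reps < 1:
        raise ValueError("reps must be ≥ 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    ec50_a = max(doses_a) if ec50_a is None else ec50_a
    ec50_b = max(doses_b) if ec50_b is None else ec50_b

    def hill_inh(d: float, ec50: float) -> float:
        return d**hill / (d**hill + ec50**hill) if d > 0 else 0.0

    signed_excess = {"bliss-independent": 0.0, "synergistic": excess, "antagonistic": -excess}[model]
    rows = []
    for rep in range(1, reps + 1):
        for da in [0.0, *sorted(doses_a)]:
            for db in [0.0, *sorted(doses_b)]:
                ia, ib = hill_inh(da, ec50_a), hill_inh(db, ec50_b)
                if da == 0 and db == 0:
                    viability = 100.0
                else:
                    if da > 0 and db > 0:
                        inh = ia + ib - ia * ib + signed_excess / 100.0
                    else:
                        inh = max(ia, ib)
                    inh = min(max(inh, 0.0), 1.0)
                    viability = 100.0 * (1.0 - inh) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                    viability = max(viability, 0.0)
                rows.append({"dose_a": da, "dose_b": db, "replicate": rep, "viability": viability})
    grid = DoseGrid(pd.DataFrame(rows))
    truth = GroundTruth(interaction_model=model, planted_excess=signed_excess)
    return grid, truth


def clinical_to_survival(clinical: pd.DataFrame, endpoint: str = "OS") -> SurvivalTable:
    """View a clinical table as a SurvivalTable for one endpoint."""
    cols = clinical[["subject", "time", "event"]].copy()
    cols["endpoint"] = endpoint
    return SurvivalTable(cols)
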