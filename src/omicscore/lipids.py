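"""Lipid nomenclature, selection rules, fatty-acyl composition and tracer
quantities.

Lipid species are written ``CLASS(C1:D1/C2:D2/...)`` with one ``carbons:double
bonds`` token per acyl chain, e.g. ``TG(16:0/18:1/16:1)``, or in sum notation
``TG(52:2)`` when only the total composition is known.  Whether a single token
is one explicit chain or a sum is decided by the class arity (TG carries three
chains, DG/PC/PE/… two, lyso and CE species one).  Ether/oxidized modifiers
are rejected rather than guessed.

Downstream quantities:

- chain composition — frequency of each acyl chain among all chain
  occurrences of the selected (explicit-chain) species;
- desaturation index — ratio of a monounsaturated FA to its saturated
  precursor (e.g. 16:1/16:0), a readout of SCD1 desaturase activity;
- tracer quantities from a uniformly 13C-labeled palmitate pulse —
  FA uptake = (labeled FA initially in medium − labeled FA remaining)
  per mg protein, and desaturase activity = labeled monounsaturated /
  labeled saturated FA;
- back-calculation of FA concentrations from internal-standard response
  ratios via a linear calibration curve.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# class → number of acyl chains in a fully specified name
CLASS_ARITY: dict[str, int] = {
    "MG": 1, "DG": 2, "TG": 3,
    "PC": 2, "PE": 2, "PG": 2, "PI": 2, "PS": 2, "PA": 2,
    "CL": 4, "SM": 2, "CER": 2, "dhCER": 2,
    "MGDG": 2, "DGDG": 2,
    "CE": 1, "FA": 1,
    "lyso.PC": 1, "lyso.PE": 1, "lyso.PG": 1, "lyso.PI": 1, "lyso.PS": 1, "lyso.PA": 1,
    "plasmenyl.PC": 2, "plasmenyl.PE": 2,
}

_NAME_RE = re.compile(r"^(?P<cls>[A-Za-z]+(?:\.[A-Za-z]+)?)\((?P<chains>[^()]*)\)$")
_CHAIN_RE = re.compile(r"^(?P<c>\d+):(?P<d>\d+)$")


@dataclass(frozen=True)
class Chain:
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons <= 0:
            raise ValueError(f"chain carbons must be positive, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double bonds must be ≥ 0")

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


@dataclass
class LipidSpecies:
    class_code: str
    chains: list[Chain]
    sum_notation: bool
    raw_name: str

    def canonical_name(self) -> str:
        return f"{self.class_code}({'/'.join(str(c) for c in self.chains)})"


def parse_chain(token: str) -> Chain:
    m = _CHAIN_RE.match(token.strip())
    if not m:
        raise ValueError(f"malformed chain token {token!r} (expected carbons:double_bonds)")
    return Chain(int(m.group("c")), int(m.group("d")))


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse ``CLASS(C:D/...)`` into class code and acyl chains.

    A single chain token for a multi-chain class is read as sum notation;
    a token count matching the class arity gives explicit chains.  Unknown
    classes and chain counts inconsistent with the arity are errors.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"unparseable lipid name {name!r}")
    cls = m.group("cls")
    if cls not in CLASS_ARITY:
        raise ValueError(f"unknown lipid class {cls!r} in {name!r}")
    tokens = [t for t in m.group("chains").split("/") if t]
    if not tokens:
        raise ValueError(f"no chains in lipid name {name!r}")
    chains = [parse_chain(t) for t in tokens]
    arity = CLASS_ARITY[cls]
    if len(chains) == arity:
        return LipidSpecies(cls, chains, sum_notation=False, raw_name=name)
    if len(chains) == 1 and arity > 1:
        return LipidSpecies(cls, chains, sum_notation=True, raw_name=name)
    raise ValueError(
        f"{name!r}: {len(chains)} chains but class {cls} carries {arity}"
    )


def select_altered_lipids(
    diff: pd.DataFrame, fdr_max: float = 0.25, min_abs_log2fc: float = 0.0
) -> pd.DataFrame:
    """Keep records with fdr < fdr_max and |log2FC| > min_abs_log2fc.

    Both inequalities are strict.  The returned subset gains a ``direction``
    refresh column split purely by the sign of log2FC.
    """
    if "fdr" not in diff.columns or "log2FC" not in diff.columns:
        raise ValueError("diff table needs 'fdr' and 'log2FC' columns")
    keep = (diff.fdr < fdr_max) & (diff.log2FC.abs() > min_abs_log2fc)
    out = diff.loc[keep.fillna(False)].copy()
    out["sign"] = np.where(out.log2FC > 0, "up", "down")
    return out


def chain_composition(
    species: list[LipidSpecies], mode: str = "occurrence"
) -> tuple[pd.Series, int]:
    """Frequency of each acyl chain among the given species.

    ``mode='occurrence'`` (default) counts every chain occurrence once and
    divides by the total number of occurrences; ``mode='presence'`` counts a
    chain at most once per species and divides by the total of such
    presences.  Sum-notation species are excluded; their count is returned
    alongside the frequency table.  Frequencies sum to 1.
    """
    if mode not in ("occurrence", "presence"):
        raise ValueError(f"unknown mode {mode!r}")
    explicit = [s for s in species if not s.sum_notation]
    n_skipped = len(species) - len(explicit)
    if not explicit:
        raise ValueError("no explicit-chain species to count (all sum notation or empty)")
    counts: dict[str, int] = {}
    for sp in explicit:
        chains = [str(c) for c in sp.chains]
        if mode == "presence":
            chains = sorted(set(chains))
        for ch in chains:
            counts[ch] = counts.get(ch, 0) + 1
    freq = pd.Series(counts, dtype=float).sort_index()
    freq /= freq.sum()
    return freq, n_skipped


def desaturation_index(
    abundances: dict[str, float] | pd.Series,
    pairs: list[tuple[str, str]] = (("16:1", "16:0"), ("14:1", "14:0")),
) -> pd.DataFrame:
    """Ratio of unsaturated to saturated chain abundance per pair.

    Pairs with a missing member or zero saturated abundance are reported
    with a NaN ratio and the failure reason; the remaining pairs are still
    returned.
    """
    ab = pd.Series(abundances, dtype=float)
    rows = []
    for unsat, sat in pairs:
        if unsat not in ab.index or sat not in ab.index:
            rows.append({"unsaturated": unsat, "saturated": sat, "ratio": np.nan,
                         "error": "missing chain abundance"})
        elif ab[sat] <= 0:
            rows.append({"unsaturated": unsat, "saturated": sat, "ratio": np.nan,
                         "error": "zero saturated denominator"})
        else:
            rows.append({"unsaturated": unsat, "saturated": sat,
                         "ratio": float(ab[unsat] / ab[sat]), "error": None})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tracer quantities


def tracer_uptake(
    initial_medium_labeled: float, remaining_medium_labeled: float, protein_mg: float
) -> tuple[float, bool]:
    """Labeled-FA uptake in nmol per mg protein.

    (initial − remaining) / protein; a negative difference (more label in the
    spent medium than was added) is flagged as a measurement inconsistency
    but still returned.
    """
    if initial_medium_labeled < 0 or remaining_medium_labeled < 0:
        raise ValueError("labeled amounts must be ≥ 0")
    if protein_mg <= 0:
        raise ValueError(f"protein mass must be positive, got {protein_mg}")
    diff = initial_medium_labeled - remaining_medium_labeled
    return diff / protein_mg, diff < 0


def desaturase_activity(labeled_mono: float, labeled_sat: float) -> float:
    """Ratio of labeled monounsaturated to labeled saturated FA."""
    if labeled_mono < 0 or labeled_sat < 0:
        raise ValueError("labeled amounts must be ≥ 0")
    if labeled_sat == 0:
        raise ValueError("zero labeled saturated FA denominator")
    return labeled_mono / labeled_sat


def labeled_fraction(labeled: float, total: float) -> float:
    """Fraction of a pool carrying label (de novo synthesis readout)."""
    if total <= 0:
        raise ValueError("total pool must be positive")
    if labeled < 0 or labeled > total:
        raise ValueError("labeled amount must lie in [0, total]")
    return labeled / total


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationCurve:
    """Linear response-ratio calibration: ratio = slope·concentration + intercept."""

    concentrations: np.ndarray
    ratios: np.ndarray
    slope: float = field(init=False, default=np.nan)
    intercept: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if len(np.unique(self.concentrations)) < 2:
            raise ValueError("calibration needs ≥2 distinct concentrations")
        fit = stats.linregress(self.concentrations, self.ratios)
        if fit.slope == 0:
            raise ValueError("calibration slope is zero; ratios carry no signal")
        self.slope, self.intercept = float(fit.slope), float(fit.intercept)

    @property
    def fitted(self) -> bool:
        return np.isfinite(self.slope) and self.slope != 0


def concentration_from_calibration(
    ratio: float, curve: CalibrationCurve
) -> tuple[float, bool]:
    """Inverse-predict concentration = (ratio − intercept)/slope.

    Returns ``(concentration, extrapolated)``; the flag is set when the ratio
    falls outside the calibrated response range.
    """
    if not curve.fitted:
        raise ValueError("calibration curve is not fitted")
    conc = (ratio - curve.intercept) / curve.slope
    lo, hi = curve.ratios.min(), curve.ratios.max()
    return float(conc), bool(ratio < lo or ratio > hi)
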