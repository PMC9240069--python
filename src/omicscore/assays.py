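"""Closed-form assay quantities: inhibition, Bliss synergy, CTCF and
ChIP-qPCR fold enrichment.

Bliss independence predicts the combined inhibition of two non-interacting
drugs as e = iA + iB − iA·iB (inhibitions as fractions).  The per-cell Bliss
excess is (observed − expected) in percentage points; the grid-mean excess is
the synergy score, called synergy when strictly > 10 and antagonism when
strictly < −10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


def inhibition_from_viability(viability: float) -> tuple[float, bool]:
    """inhibition% = 100 − viability%, clipped to [0, 100] with a flag.

    Viability above 100% (growth beyond the untreated control) clips to an
    inhibition of 0; negative viability is an input error.
    """
    if viability < 0:
        raise ValueError(f"viability must be ≥ 0, got {viability}")
    raw = 100.0 - viability
    clipped = min(max(raw, 0.0), 100.0)
    return clipped, clipped != raw


@dataclass
class DoseGrid:
    """Replicated two-drug viability grid in percent of untreated control.

    ``table`` is long-format with columns ``dose_a``, ``dose_b``,
    ``replicate``, ``viability``; the grid must contain single-agent margins
    (dose 0 of the partner drug) for every combination cell, and the
    untreated cell (0, 0) is 100 by normalization.
    """

    table: pd.DataFrame
    doses_a: np.ndarray = field(init=False)
    doses_b: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        required = {"dose_a", "dose_b", "replicate", "viability"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"dose grid needs columns {sorted(required)}")
        if (self.table.viability < 0).any():
            raise ValueError("viability must be ≥ 0")
        self.doses_a = np.sort(self.table.dose_a.unique())
        self.doses_b = np.sort(self.table.dose_b.unique())

    def mean_viability(self) -> pd.DataFrame:
        """Replicate-mean viability per (dose_a, dose_b) cell."""
        return self.table.groupby(["dose_a", "dose_b"], as_index=False).viability.mean()


@dataclass
class BlissResult:
    per_cell: pd.DataFrame  # dose_a, dose_b, observed, expected, excess (pp)
    mean_score: float
    call: str  # synergy | additive | antagonism
    clipped_cells: int


def bliss_synergy(grid: DoseGrid, replicate_mode: str = "mean_viability") -> BlissResult:
    """Bliss excess over the combination cells of a dose grid.

    ``replicate_mode='mean_viability'`` (default) averages replicate
    viabilities per cell before scoring; ``'per_replicate'`` scores each
    replicate against its own margins and averages the resulting excesses
    (the two agree on complete grids).  Every combination cell requires both
    single-agent margins; a missing margin is an error naming the cell.
    """
    if replicate_mode not in ("mean_viability", "per_replicate"):
        raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
    if replicate_mode == "mean_viability":
        frames = [grid.mean_viability()]
    else:
        frames = [g.drop(columns="replicate") for _, g in grid.table.groupby("replicate")]

    per_cell_frames = []
    clipped = 0
    for cells in frames:
        lookup: Mapping[tuple[float, float], float] = {
            (r.dose_a, r.dose_b): r.viability for r in cells.itertuples()
        }
        rows = []
        for (da, db), viab in lookup.items():
            if da == 0 or db == 0:
                continue
            if (da, 0.0) not in lookup:
                raise ValueError(f"missing single-agent margin for dose_a={da}")
            if (0.0, db) not in lookup:
                raise ValueError(f"missing single-agent margin for dose_b={db}")
            i_obs, c0 = inhibition_from_viability(viab)
            i_a, c1 = inhibition_from_viability(lookup[(da, 0.0)])
            i_b, c2 = inhibition_from_viability(lookup[(0.0, db)])
            clipped += sum([c0, c1, c2])
            fa, fb, fo = i_a / 100.0, i_b / 100.0, i_obs / 100.0
            expected = fa + fb - fa * fb
            rows.append(
                {"dose_a": da, "dose_b": db, "observed": fo * 100, "expected": expected * 100,
                 "excess": (fo - expected) * 100}
            )
        if not rows:
            raise ValueError("grid has no combination cells")
        per_cell_frames.append(pd.DataFrame(rows))

    if replicate_mode == "mean_viability":
        per_cell = per_cell_frames[0]
    else:
        per_cell = (
            pd.concat(per_cell_frames).groupby(["dose_a", "dose_b"], as_index=False).mean()
        )
    mean_score = float(per_cell.excess.mean())
    # strict >10 / <−10 calls, with an epsilon so a score exactly at the
    # boundary is not tipped over by floating-point round-off
    if mean_score > 10 + 1e-9:
        call = "synergy"
    elif mean_score < -10 - 1e-9:
        call = "antagonism"
    else:
        call = "additive"
    return BlissResult(per_cell.sort_values(["dose_a", "dose_b"]).reset_index(drop=True),
                       mean_score, call, clipped)


def ctcf(integrated_density: float, area: float, background_mean: float) -> tuple[float, bool]:
    """Corrected total cell fluorescence = integrated density − area × background mean.

    Negative results (background brighter than the cell) are flagged, not
    suppressed.
    """
    if integrated_density < 0 or area < 0 or background_mean < 0:
        raise ValueError("CTCF inputs must be ≥ 0")
    value = integrated_density - area * background_mean
    return value, value < 0


def chip_fold_enrichment(
    ct: Mapping[tuple[str, str], float], negative_control_region: str
) -> pd.Series:
    """ChIP-qPCR fold enrichment per region by the 2^−ΔΔCt method.

    ``ct`` maps (region, 'IP'|'input') → Ct.  ΔCt = Ct(IP) − Ct(input) per
    region; ΔΔCt subtracts the negative-control region's ΔCt; fold =
    2^(−ΔΔCt), so the negative control is 1 by construction.
    """
    regions = sorted({region for region, _ in ct})
    if negative_control_region not in regions:
        raise ValueError(f"negative control region {negative_control_region!r} missing from Ct data")

    def delta(region: str) -> float:
        try:
            return ct[(region, "IP")] - ct[(region, "input")]
        except KeyError as exc:
            raise ValueError(f"missing Ct for region {region!r}: {exc}") from exc

    ref = delta(negative_control_region)
    folds = {region: 2.0 ** (-(delta(region) - ref)) for region in regions}
    return pd.Series(folds).sort_index()
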