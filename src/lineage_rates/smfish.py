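"""Accumulation rates from smFISH spot counts, and concordance with scRNA-seq.

Single-molecule FISH counts mature transcripts as diffraction-limited spots
in fixed embryos; DAPI nuclei counts stage each embryo, and a bundled timing
table converts the stage to minutes after first cleavage.  The rate for a
gene in a cell is the ordinary-least-squares slope of per-cell spot count
versus time across embryos sampled inside a user-chosen staging window (the
interval between the two divisions bracketing maximal expression).  Labels
covering a set of equivalent sisters (e.g. "MSx" for both MS daughters) are
normalised to per-cell counts by dividing by the number of expressing cells.

Concordance with sequencing-derived rates is summarised by the Pearson
correlation and the fraction of genes whose two estimates agree within
two-fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lineage import LineageTree, TimingTable

__all__ = [
    "RateComparison",
    "smfish_rate",
    "fold_difference",
    "method_concordance",
    "expressing_cell_count",
]

OBS_COLUMNS = ("embryo_id", "gene", "cell_label", "nuclei_count", "spot_count")


@dataclass(frozen=True)
class RateComparison:
    gene: str
    rate_fish: float
    rate_seq: float

    @property
    def fold_difference(self) -> float:
        return fold_difference(self.rate_fish, self.rate_seq)


def expressing_cell_count(cell_label: str, tree: LineageTree | None = None) -> int:
    """Number of equivalent cells covered by a label.

    A plain cell name covers one cell.  The "<parent>x" shorthand covers
    every daughter of <parent> (2 in a binary lineage); without a tree the
    trailing-x convention still resolves to 2.
    """
    if cell_label.endswith("x"):
        base = cell_label[:-1]
        if tree is not None and base in tree:
            return max(len(tree.children_of(base)), 1)
        return 2
    return 1


def smfish_rate(
    observations: pd.DataFrame,
    timing: TimingTable,
    window: tuple[int, int],
    tree: LineageTree | None = None,
) -> float:
    """Per-cell accumulation rate (transcripts/min) by OLS over staged embryos.

    ``observations`` holds rows for one gene and one cell label with
    columns nuclei_count and spot_count; ``window`` is the inclusive
    (start, end) nuclei-count range between the two divisions of maximal
    expression.  Counts for multi-cell labels are divided by the number of
    expressing cells before the fit.
    """
    obs = observations
    missing = {"nuclei_count", "spot_count"} - set(obs.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    lo, hi = window
    obs = obs[(obs["nuclei_count"] >= lo) & (obs["nuclei_count"] <= hi)]
    if len(obs) < 2:
        raise ValueError("need at least 2 observations inside the staging window")
    times = obs["nuclei_count"].map(timing.nuclei_to_time).to_numpy(dtype=float)
    if np.ptp(times) == 0:
        raise ValueError("zero time spread inside the window; cannot fit a slope")
    counts = obs["spot_count"].to_numpy(dtype=float)
    if "cell_label" in obs.columns:
        n_cells = obs["cell_label"].map(
            lambda lbl: expressing_cell_count(str(lbl), tree)
        ).to_numpy(dtype=float)
        counts = counts / n_cells
    slope, _ = np.polyfit(times, counts, 1)
    return float(slope)


def fold_difference(rate_a: float, rate_b: float) -> float:
    """Symmetric fold difference max/min ≥ 1 between two positive rates."""
    if rate_a <= 0 or rate_b <= 0:
        raise ValueError("rates must be positive")
    return max(rate_a, rate_b) / min(rate_a, rate_b)


def method_concordance(
    comparisons: Sequence[RateComparison] | Iterable[RateComparison],
) -> dict:
    """Pearson r and within-2-fold fraction over (smFISH, scRNA-seq) rate pairs."""
    comps = list(comparisons)
    if len(comps) < 3:
        raise ValueError("need at least 3 rate comparisons")
    fish = np.array([c.rate_fish for c in comps])
    seq = np.array([c.rate_seq for c in comps])
    if fish.std() == 0 or seq.std() == 0:
        return {
            "pearson_r": float("nan"),
            "within_2fold_fraction": float(
                np.mean([c.fold_difference <= 2.0 for c in comps])
            ),
            "n": len(comps),
            "degenerate": True,
        }
    r, _ = stats.pearsonr(fish, seq)
    frac = float(np.mean([c.fold_difference <= 2.0 for c in comps]))
    return {"pearson_r": float(r), "within_2fold_fraction": frac, "n": len(comps),
            "degenerate": False}


def comparisons_frame(comparisons: Iterable[RateComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "rate_fish": c.rate_fish,
                "rate_seq": c.rate_seq,
                "fold_difference": c.fold_difference,
            }
            for c in comparisons
        ]
    )
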