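"""Absolute transcript accumulation rates from calibrated expression data.

Per-cell TPM values are calibrated to absolute molecule counts using the
cell's volume fraction and a whole-embryo total of 8,000,000 mRNA molecules
(mRNA content scales with cell size during reductive cleavage).  For every
parent→daughter edge of the lineage two metrics are computed per gene:

* **AC (absolute change)** — new transcripts made during the daughter's
  cell cycle: ``(TPM_daughter − TPM_parent) × daughter volume fraction ×
  8e6 / 1e6``.  Subtracting the parent TPM at the daughter's volume removes
  the inherited contribution under the assumption that daughters inherit
  the parental concentration.
* **FC (fold change)** — pseudocounted daughter/parent ratio on the
  absolute-count scale, separating de-novo transcription from transcripts
  already abundant in the parent.

Genes with > 12.5 TPM in the one-cell embryo (P0), i.e. > 100 calibrated
molecules, are maternal and excluded.  AC and FC jointly place each
gene/edge in a rate category (high/medium/low, plus "none" for the
uncovered AC ≤ 1 or FC ≤ 1 region), and AC over the daughter cycle length
gives transcripts per minute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .lineage import LineageTree

__all__ = [
    "CalibrationParams",
    "ExpressionMatrix",
    "RateRecord",
    "pseudobulk_median",
    "tpm_to_count",
    "is_maternal",
    "absolute_change",
    "fold_change",
    "classify_rate",
    "rate_per_minute",
    "build_rate_table",
    "rate_table_frame",
    "strict_category_genes",
    "cluster_rate_profiles",
]

log = logging.getLogger(__name__)

CATEGORY_ORDER = ("none", "low", "medium", "high")
_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}


@dataclass(frozen=True)
class CalibrationParams:
    """Calibration and thresholding constants.

    embryo_total: total mRNA molecules per embryo (8e6, anchored to smFISH
    counts of endodermal genes).  maternal_tpm_threshold: P0 TPM above which
    a gene is maternal (12.5 TPM = 100 molecules at P0).  fc_pseudocount:
    molecules added to numerator and denominator of FC (stabilises the
    ratio when the parent count is 0).
    """

    embryo_total: float = 8_000_000.0
    maternal_tpm_threshold: float = 12.5
    fc_pseudocount: float = 10.0

    def __post_init__(self):
        if min(self.embryo_total, self.maternal_tpm_threshold, self.fc_pseudocount) <= 0:
            raise ValueError("calibration parameters must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CalibrationParams":
        """Load from a YAML mapping with any of the field names."""
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        allowed = {"embryo_total", "maternal_tpm_threshold", "fc_pseudocount"}
        unknown = set(cfg) - allowed
        if unknown:
            raise ValueError(f"unknown calibration keys: {sorted(unknown)}")
        # YAML 1.1 reads "4.0e6" (no sign) as a string; coerce numerics
        return cls(**{k: float(v) for k, v in cfg.items()})


@dataclass
class ExpressionMatrix:
    """Genes × cells expression values with a unit tag.

    ``values`` is a DataFrame indexed by gene with one column per named
    cell; unit is "TPM" or "absolute_count".
    """

    values: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cells(self) -> list[str]:
        return list(self.values.columns)

    def check_cells(self, tree: LineageTree) -> None:
        unknown = [c for c in self.cells if c not in tree]
        if unknown:
            raise ValueError(f"cells not in lineage tree: {unknown}")


@dataclass(frozen=True)
class RateRecord:
    """AC/FC/rate/category for one gene on one parent→daughter edge."""

    gene: str
    parent_cell: str
    daughter_cell: str
    stage: str
    ac: float
    fc: float
    rate_per_min: float
    category: str


def pseudobulk_median(
    replicate_values: Mapping[str, np.ndarray | Sequence[float]],
    tossed_flags: Mapping[str, Sequence[bool]] | None = None,
    genes: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Median TPM over non-tossed replicates, per cell.

    ``replicate_values[cell]`` is a (genes × replicates) array of TPM;
    ``tossed_flags[cell]`` marks replicates excluded by QC ("tossed").
    """
    columns = {}
    for cell, mat in replicate_values.items():
        arr = np.asarray(mat, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        keep = np.ones(arr.shape[1], dtype=bool)
        if tossed_flags and cell in tossed_flags:
            keep = ~np.asarray(tossed_flags[cell], dtype=bool)
        if not keep.any():
            raise ValueError(f"all replicates tossed for cell {cell!r}")
        columns[cell] = np.median(arr[:, keep], axis=1)
    df = pd.DataFrame(columns)
    if genes is not None:
        df.index = pd.Index(genes, name="gene")
    return ExpressionMatrix(df, unit="TPM")


def tpm_to_count(
    tpm: float | np.ndarray,
    volume_fraction: float,
    params: CalibrationParams = CalibrationParams(),
) -> float | np.ndarray:
    """Calibrate TPM to absolute molecules: tpm/1e6 × volume × embryo total."""
    if not 0 < volume_fraction <= 1:
        raise ValueError("volume_fraction must be in (0, 1]")
    if np.any(np.asarray(tpm) < 0):
        raise ValueError("TPM must be non-negative")
    return tpm / 1e6 * volume_fraction * params.embryo_total


def is_maternal(p0_tpm: float, params: CalibrationParams = CalibrationParams()) -> bool:
    """Maternal gene: strictly above the P0 TPM threshold (12.5 TPM = 100 molecules)."""
    return p0_tpm > params.maternal_tpm_threshold


def absolute_change(
    tpm_parent: float,
    tpm_daughter: float,
    daughter_volume_fraction: float,
    params: CalibrationParams = CalibrationParams(),
) -> float:
    """AC: new transcripts over the daughter cycle; negative means net loss."""
    return float(
        (tpm_daughter - tpm_parent) / 1e6 * daughter_volume_fraction * params.embryo_total
    )


def fold_change(
    count_parent: float,
    count_daughter: float,
    params: CalibrationParams = CalibrationParams(),
) -> float:
    """Pseudocounted daughter/parent ratio on the absolute-count scale."""
    if count_parent < 0 or count_daughter < 0:
        raise ValueError("counts must be non-negative")
    p = params.fc_pseudocount
    return (count_daughter + p) / (count_parent + p)


def _rank_ac(ac: float) -> int:
    if ac > 200:
        return _RANK["high"]
    if ac > 50:
        return _RANK["medium"]
    if ac > 1:
        return _RANK["low"]
    return _RANK["none"]


def _rank_fc(fc: float) -> int:
    if fc > 10:
        return _RANK["high"]
    if fc > 5:
        return _RANK["medium"]
    if fc > 1:
        return _RANK["low"]
    return _RANK["none"]


def classify_rate(ac: float, fc: float) -> str:
    """Joint AC/FC rate category.

    High needs AC > 200 and FC > 10; one high with the other medium gives
    medium; FC in (1, 5] caps the category at low regardless of AC; AC ≤ 1
    or FC ≤ 1 is "none" (no net accumulation).  Equivalently, the category
    is the lower of the two per-metric ranks, which is the unique monotone
    completion of those rules.
    """
    return CATEGORY_ORDER[min(_rank_ac(ac), _rank_fc(fc))]


def rate_per_minute(ac: float, cycle_min: float) -> float:
    """Accumulation rate in transcripts/min: AC over the daughter cycle length."""
    if cycle_min <= 0:
        raise ValueError("cycle length must be positive")
    return ac / cycle_min


def build_rate_table(
    expr: ExpressionMatrix,
    tree: LineageTree,
    params: CalibrationParams = CalibrationParams(),
) -> list[RateRecord]:
    """One RateRecord per zygotic gene per parent→daughter edge.

    Maternal genes (P0 TPM above threshold) are excluded entirely; edges
    whose parent or daughter lacks expression data are skipped with a
    warning (a missing parent is treated as missing, not zero, to avoid
    dropout-inflated fold changes).  Order is deterministic: gene, then
    daughter name.
    """
    if expr.unit != "TPM":
        raise ValueError("build_rate_table expects a TPM matrix")
    expr.check_cells(tree)
    vals = expr.values
    root = tree.root

    if root in vals.columns:
        maternal = vals[root] > params.maternal_tpm_threshold
    else:
        log.warning("no %s column; maternal filter not applied", root)
        maternal = pd.Series(False, index=vals.index)

    usable_edges = []
    for parent, daughter in tree.edges():
        if daughter not in vals.columns:
            continue
        if parent not in vals.columns:
            log.warning("edge %s→%s skipped: parent has no expression data", parent, daughter)
            continue
        usable_edges.append((parent, daughter))

    records: list[RateRecord] = []
    for gene in vals.index:
        if maternal[gene]:
            continue
        row = vals.loc[gene]
        for parent, daughter in usable_edges:
            vol_d = tree.volume_fraction(daughter)
            ac = absolute_change(row[parent], row[daughter], vol_d, params)
            # parent transcripts re-scaled to the daughter's volume: the FC
            # denominator is what the daughter inherits at parental
            # concentration, mirroring the AC formula
            fc = fold_change(
                tpm_to_count(row[parent], vol_d, params),
                tpm_to_count(row[daughter], vol_d, params),
                params,
            )
            cyc = tree.cycle_duration(daughter)
            records.append(
                RateRecord(
                    gene=gene,
                    parent_cell=parent,
                    daughter_cell=daughter,
                    stage=tree[daughter].stage,
                    ac=ac,
                    fc=fc,
                    rate_per_min=rate_per_minute(ac, cyc),
                    category=classify_rate(ac, fc),
                )
            )
    records.sort(key=lambda r: (r.gene, r.daughter_cell))
    return records


def rate_table_frame(records: Iterable[RateRecord]) -> pd.DataFrame:
    """Rate records as a tidy DataFrame (gene, parent, daughter, stage, ...)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "parent": r.parent_cell,
                "daughter": r.daughter_cell,
                "stage": r.stage,
                "ac": r.ac,
                "fc": r.fc,
                "rate_per_min": r.rate_per_min,
                "category": r.category,
            }
            for r in records
        ]
    )


def strict_category_genes(records: Iterable[RateRecord]) -> dict[str, set[str]]:
    """Gene-level categories with the strict never-low filter.

    A gene is "high" iff it is high on at least one edge and never low on
    any edge; analogously for "medium" (among genes not already high).
    Remaining genes with at least one classified (non-"none") edge fall to
    "low".  Used for gene-architecture and motif comparisons, where a gene
    that is ever slow anywhere is not a clean fast example.
    """
    seen: dict[str, set[str]] = {}
    for r in records:
        seen.setdefault(r.gene, set()).add(r.category)
    out = {"high": set(), "medium": set(), "low": set()}
    for gene, cats in seen.items():
        never_low = "low" not in cats
        if "high" in cats and never_low:
            out["high"].add(gene)
        elif "medium" in cats and never_low:
            out["medium"].add(gene)
        elif cats - {"none"}:
            out["low"].add(gene)
    return out


def cluster_rate_profiles(ac_matrix: pd.DataFrame):
    """Average-linkage hierarchical clustering of AC profiles, Pearson distance.

    Distance between genes is 1 − Pearson correlation of their per-cell AC
    vectors; zero-variance rows get distance 1 to everything (logged).
    Returns (linkage_matrix, leaf_order, ordered_frame).
    """
    if ac_matrix.shape[0] < 2 or ac_matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 cells to cluster")
    X = ac_matrix.to_numpy(dtype=float)
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning(
            "%d zero-variance rows; their Pearson distance is defined as 1",
            int(degenerate.sum()),
        )
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[degenerate] = 1.0
    unit = centered / norms[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[degenerate, :] = 1.0
    dist[:, degenerate] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    order = sch.leaves_list(Z)
    return Z, order, ac_matrix.iloc[order]


def write_rate_table(records: Iterable[RateRecord], path: str | Path) -> None:
    rate_table_frame(records).to_csv(path, sep="\t", index=False)
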