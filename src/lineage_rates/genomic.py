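"""Gene architecture, chromosomal position and promoter-motif enrichment.

Rapidly accumulating zygotic genes share structural features — short
primary transcripts, few and short introns, few isoforms — and cluster on
particular chromosomes and chromosome arms.  This module computes those
statistics from gene models, consolidates candidate transcription start
sites from multiple sources into a single TSS per gene, extracts 500-bp
promoters, and measures motif occurrence and positional enrichment across
rate categories (chi-square homogeneity tests with Wilson confidence
intervals and Benjamini–Hochberg adjustment; Fisher's exact test for 2×2
category associations).

Coordinate conventions: GFF3 input is 1-based inclusive and BED input
0-based half-open; internally everything is 0-based half-open.  Offsets
relative to the TSS are negative upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .motifs import MotifHit, reverse_complement

__all__ = [
    "GeneModel",
    "TssCandidate",
    "read_gff3",
    "read_tss_bed",
    "consolidate_tss",
    "extract_promoter",
    "intron_density",
    "occurrence_enrichment",
    "tss_positional_profile",
    "chromosome_enrichment",
    "positional_clusters",
    "category_association",
]

log = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """One gene: longest-isoform span and exon/intron structure.

    Coordinates are 0-based half-open.  "Gene length" throughout the
    package means the primary (unspliced) transcript span of the longest
    isoform.  The TSS defaults to the strand-aware 5' end of that span.
    """

    gene: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    n_isoforms: int = 1
    tss: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError("gene span must be non-empty")
        self.exons = sorted(tuple(e) for e in self.exons)
        if self.tss is None:
            self.tss = self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive sorted exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass(frozen=True)
class TssCandidate:
    gene: str
    source: str
    chromosome: str
    position: int  # 0-based
    strand: str = "+"


# -- input formats ------------------------------------------------------


def _gff3_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Gene models from a GFF3 file (gene / mRNA / exon features).

    Per gene, the longest mRNA defines the span, exons and TSS; the
    isoform count is the number of mRNA children.  GFF3 1-based inclusive
    coordinates are converted to 0-based half-open.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            a = _gff3_attributes(attrs)
            s0, e0 = int(start) - 1, int(end)  # to 0-based half-open
            if ftype == "gene":
                gid = a.get("ID", a.get("Name", ""))
                genes[gid] = {
                    "chrom": chrom, "strand": strand, "start": s0, "end": e0,
                    "name": a.get("Name", gid), "mrnas": {},
                }
            elif ftype in ("mRNA", "transcript"):
                gid = a.get("Parent", "")
                mid = a.get("ID", "")
                mrna_to_gene[mid] = gid
                if gid in genes:
                    genes[gid]["mrnas"][mid] = {"start": s0, "end": e0, "exons": []}
            elif ftype == "exon":
                mid = a.get("Parent", "")
                gid = mrna_to_gene.get(mid)
                if gid in genes and mid in genes[gid]["mrnas"]:
                    genes[gid]["mrnas"][mid]["exons"].append((s0, e0))
    models: dict[str, GeneModel] = {}
    for gid, g in genes.items():
        name = g["name"]
        if g["mrnas"]:
            longest = max(g["mrnas"].values(), key=lambda m: m["end"] - m["start"])
            start, end, exons = longest["start"], longest["end"], longest["exons"]
            n_iso = len(g["mrnas"])
        else:
            start, end, exons, n_iso = g["start"], g["end"], [], 1
        models[name] = GeneModel(
            gene=name, chromosome=g["chrom"], strand=g["strand"],
            start=start, end=end, exons=exons, n_isoforms=n_iso,
        )
    return models


def read_tss_bed(path: str | Path, source: str) -> list[TssCandidate]:
    """TSS candidates from BED (0-based half-open; name = gene).

    The TSS is the interval start for + strand and end − 1 for −.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            chrom, start, end, gene = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            pos = start if strand == "+" else end - 1
            out.append(TssCandidate(gene, source, chrom, pos, strand))
    return out


# -- TSS consolidation and promoters ------------------------------------


def consolidate_tss(
    candidates: Mapping[str, Sequence[TssCandidate]],
    window: int = 10,
    source_priority: Sequence[str] | None = None,
) -> dict[str, TssCandidate]:
    """One TSS per gene from up to three candidate sources.

    If two or more sources agree within ``window`` bp, the consolidated
    TSS is the median of the agreeing coordinates (largest agreeing group;
    ties broken toward the higher-priority source).  Otherwise the
    highest-priority source wins.  Genes whose candidates sit on different
    chromosomes are dropped with a log entry.
    """
    result: dict[str, TssCandidate] = {}
    for gene, cands in candidates.items():
        cands = list(cands)
        if not cands:
            log.warning("gene %s has no TSS candidate; dropped", gene)
            continue
        if len({c.chromosome for c in cands}) > 1:
            log.warning("gene %s: TSS candidates on different chromosomes; dropped", gene)
            continue
        prio = {s: i for i, s in enumerate(source_priority or [])}

        def rank(c: TssCandidate) -> int:
            return prio.get(c.source, len(prio))

        cands.sort(key=lambda c: (c.position, rank(c)))
        pos = np.array([c.position for c in cands])
        # largest group of mutually agreeing candidates via sliding range
        best: list[int] = []
        for i in range(len(pos)):
            group = [j for j in range(i, len(pos)) if pos[j] - pos[i] <= window]
            if len(group) > len(best) or (
                len(group) == len(best)
                and best
                and min(rank(cands[j]) for j in group) < min(rank(cands[j]) for j in best)
            ):
                best = group
        if len(best) >= 2:
            agreed = int(round(float(np.median(pos[best]))))
            anchor = min((cands[j] for j in best), key=rank)
            result[gene] = TssCandidate(
                gene, "consolidated", anchor.chromosome, agreed, anchor.strand
            )
        else:
            result[gene] = min(cands, key=rank)
    return result


def extract_promoter(
    genome,
    chromosome: str,
    tss: int,
    strand: str,
    length: int = 500,
) -> tuple[str, bool]:
    """Promoter sequence: ``length`` bases upstream of the TSS, coding strand.

    For + strand this is [tss − length, tss) of the forward strand; for −
    strand the reverse complement of [tss + 1, tss + 1 + length).  Clipped
    at chromosome ends; returns (sequence, clipped_flag).  ``genome`` is a
    pyfaidx.Fasta or any mapping of chromosome → sequence string.
    """
    chrom_seq = genome[chromosome]
    chrom_len = len(chrom_seq)
    if not 0 <= tss < chrom_len:
        raise ValueError(f"TSS {tss} outside chromosome {chromosome!r} (length {chrom_len})")
    if strand == "+":
        start = max(0, tss - length)
        seq = str(chrom_seq[start:tss])
        clipped = tss - length < 0
    elif strand == "-":
        end = min(chrom_len, tss + 1 + length)
        seq = reverse_complement(str(chrom_seq[tss + 1 : end]))
        clipped = tss + 1 + length > chrom_len
    else:
        raise ValueError("strand must be '+' or '-'")
    return seq.upper(), clipped


# -- architecture statistics --------------------------------------------


def intron_density(gene: GeneModel) -> float:
    """Introns per kilobase of primary transcript."""
    if gene.length <= 0:
        raise ValueError("zero-length gene span")
    return len(gene.introns) / (gene.length / 1000.0)


def positional_clusters(
    coordinates: Sequence[int], max_gap: int
) -> list[dict]:
    """Single-linkage 1-D clustering of gene coordinates on one chromosome.

    A gene joins the current cluster when it lies within ``max_gap`` bp of
    the previous gene; returns spans and member indices in coordinate
    order (input order is irrelevant).
    """
    if len(coordinates) == 0:
        return []
    order = np.argsort(np.asarray(coordinates), kind="stable")
    coords = np.asarray(coordinates)[order]
    clusters = []
    current = [0]
    for i in range(1, len(coords)):
        if coords[i] - coords[i - 1] <= max_gap:
            current.append(i)
        else:
            clusters.append(current)
            current = [i]
    clusters.append(current)
    return [
        {
            "start": int(coords[c[0]]),
            "end": int(coords[c[-1]]),
            "n_genes": len(c),
            "members": [int(order[i]) for i in c],
        }
        for c in clusters
    ]


# -- enrichment statistics ----------------------------------------------


def occurrence_enrichment(
    hits: Iterable[MotifHit],
    gene_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-category fraction of genes with ≥1 hit of each motif.

    Categories (disjoint gene sets) are compared with a chi-square test of
    homogeneity per motif; Wilson 95% CIs per proportion; BH adjustment of
    the chi-square p-values across motifs.  Empty categories are excluded
    with a log entry.
    """
    sets = {k: v for k, v in gene_sets.items() if len(v)}
    for k in gene_sets.keys() - sets.keys():
        log.warning("category %s is empty; excluded from enrichment", k)
    if not sets:
        raise ValueError("all categories are empty")
    hit_genes: dict[str, set[str]] = {}
    for h in hits:
        hit_genes.setdefault(h.motif, set()).add(h.gene)
    rows = []
    for motif in sorted(hit_genes):
        with_hit = hit_genes[motif]
        counts = {c: len(genes & with_hit) for c, genes in sets.items()}
        totals = {c: len(genes) for c, genes in sets.items()}
        table = np.array([[counts[c], totals[c] - counts[c]] for c in sets])
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        for c in sets:
            lo, hi = proportion_confint(counts[c], totals[c], method="wilson")
            rows.append(
                {
                    "motif": motif,
                    "category": c,
                    "n_with_hit": counts[c],
                    "n_genes": totals[c],
                    "proportion": counts[c] / totals[c],
                    "ci_low": lo,
                    "ci_high": hi,
                    "chi2": chi2,
                    "p_value": p,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        per_motif = df.drop_duplicates("motif").set_index("motif")["p_value"]
        adj = pd.Series(
            multipletests(per_motif.to_numpy(), method="fdr_bh")[1], index=per_motif.index
        )
        df["p_adjusted"] = df["motif"].map(adj)
    return df


def tss_positional_profile(
    hits: Iterable[MotifHit],
    gene_sets: Mapping[str, set[str]],
    bin_width: int = 25,
    span: tuple[int, int] = (-500, 0),
) -> pd.DataFrame:
    """Normalised histogram of motif-hit offsets per category.

    Offsets are TSS-relative (negative upstream).  Densities sum to 1
    within each (motif, category); the peak bin marks where the motif
    concentrates (for the Initiator, expected at the TSS itself).
    """
    lo, hi = span
    edges = np.arange(lo, hi + bin_width, bin_width)
    rows = []
    hits = list(hits)
    for motif in sorted({h.motif for h in hits}):
        for category, genes in gene_sets.items():
            offs = [h.offset for h in hits if h.motif == motif and h.gene in genes]
            counts, _ = np.histogram(offs, bins=edges)
            dens = counts / counts.sum() if counts.sum() else counts.astype(float)
            peak = edges[int(np.argmax(counts))] if counts.sum() else np.nan
            for b, (c, d) in enumerate(zip(counts, dens)):
                rows.append(
                    {
                        "motif": motif,
                        "category": category,
                        "bin_start": int(edges[b]),
                        "bin_end": int(edges[b + 1]),
                        "count": int(c),
                        "density": float(d),
                        "peak_bin_start": peak,
                    }
                )
    return pd.DataFrame(rows)


def chromosome_enrichment(
    category_genes: Mapping[str, set[str]],
    all_genes: set[str],
    chrom_map: Mapping[str, str],
) -> pd.DataFrame:
    """Chromosome distribution per category vs the all-gene background.

    Chi-square goodness-of-fit of each category's per-chromosome counts
    against expectations from the all-gene proportions, BH-adjusted across
    categories.  Genes without a chromosome are excluded with a log entry;
    expected counts < 5 are flagged.
    """
    mapped_all = [g for g in sorted(all_genes) if g in chrom_map]
    dropped = len(all_genes) - len(mapped_all)
    if dropped:
        log.warning("%d genes without chromosome assignment excluded", dropped)
    chroms = sorted({chrom_map[g] for g in mapped_all})
    bg = pd.Series(
        pd.Categorical([chrom_map[g] for g in mapped_all], categories=chroms)
    ).value_counts().reindex(chroms)
    bg_prop = bg / bg.sum()
    rows = []
    pvals = {}
    for cat, genes in category_genes.items():
        members = [g for g in sorted(genes) if g in chrom_map]
        if not members:
            log.warning("category %s has no mapped genes; excluded", cat)
            continue
        obs = pd.Series(
            pd.Categorical([chrom_map[g] for g in members], categories=chroms)
        ).value_counts().reindex(chroms)
        expected = bg_prop * len(members)
        chi2, p = stats.chisquare(obs.to_numpy(), expected.to_numpy())
        pvals[cat] = p
        for chrom in chroms:
            rows.append(
                {
                    "category": cat,
                    "chromosome": chrom,
                    "n_genes": int(obs[chrom]),
                    "proportion": obs[chrom] / len(members),
                    "background_proportion": float(bg_prop[chrom]),
                    "expected": float(expected[chrom]),
                    "small_expected": bool(expected[chrom] < 5),
                    "chi2": float(chi2),
                    "p_value": float(p),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        cats = list(pvals)
        adj = dict(zip(cats, multipletests([pvals[c] for c in cats], method="fdr_bh")[1]))
        df["p_adjusted"] = df["category"].map(adj)
    return df


def category_association(table: Sequence[Sequence[float]]) -> dict:
    """Odds ratio, Fisher exact p and 95% CI for a 2×2 contingency table.

    Zero cells get the Haldane–Anscombe 0.5 correction for the OR and its
    Woolf CI (flagged); the p-value is always the exact hypergeometric one
    on the uncorrected table.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2×2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero margin")
    _, p = stats.fisher_exact(t)
    corrected = bool((t == 0).any())
    t_or = t + 0.5 if corrected else t
    odds = (t_or[0, 0] * t_or[1, 1]) / (t_or[0, 1] * t_or[1, 0])
    ci_low, ci_high = Table2x2(t_or).oddsratio_confint()
    return {
        "odds_ratio": float(odds),
        "p_value": float(p),
        "ci_low": float(ci_low),
        "ci_high": float(ci_high),
        "zero_cell_corrected": corrected,
    }
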