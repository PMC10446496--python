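"""Initiator-motif enrichment across rate categories on a synthetic genome.

Builds a toy genome in which high-rate promoters carry a planted Inr-like
element near the TSS far more often than low-rate or maternal promoters,
then runs the real pipeline: promoter extraction (500 bp upstream of the
TSS, strand-aware), PWM scanning with exact p-values at the 1e-4 cutoff,
occurrence enrichment with chi-square/Wilson CIs, and the TSS positional
profile.  Writes results/motif_enrichment.tsv and results/inr_profile.tsv.
"""

import numpy as np

import lineage_rates as lr
from lineage_rates.genomic import (
    extract_promoter,
    occurrence_enrichment,
    tss_positional_profile,
)
from lineage_rates.motifs import PWM, scan_promoter

from common import RESULTS, SEED

# tcAttc-style initiator with flanking information: 8 positions so the
# consensus can clear the 1e-4 cutoff (a 6-bp motif's best match cannot —
# the null probability of the consensus itself already exceeds 1e-4)
INR = PWM(
    "inr",
    np.array(
        [
            [0.10, 0.15, 0.10, 0.65],
            [0.10, 0.60, 0.10, 0.20],
            [0.85, 0.05, 0.05, 0.05],
            [0.10, 0.10, 0.10, 0.70],
            [0.15, 0.15, 0.15, 0.55],
            [0.10, 0.55, 0.15, 0.20],
            [0.10, 0.15, 0.10, 0.65],
            [0.15, 0.55, 0.15, 0.15],
        ]
    ),
)

PLANT_PROBABILITY = {"high": 0.8, "medium": 0.6, "low": 0.25, "maternal": 0.15}
GENES_PER_CATEGORY = 60
PROMOTER = 500


def synthetic_chromosome(rng, categories):
    """One chromosome of back-to-back promoters; returns (seq, gene->TSS)."""
    seq = []
    tss = {}
    genes = []
    pos = 0
    for cat, n in categories.items():
        for i in range(n):
            gene = f"{cat}-{i:03d}"
            block = rng.choice(list("ACGT"), size=PROMOTER,
                               p=[0.32, 0.18, 0.18, 0.32]).tolist()
            if rng.random() < PLANT_PROBABILITY[cat]:
                site = list(INR.consensus)
                w = len(site)
                at = PROMOTER - w - int(rng.integers(0, 4))  # at/near the TSS
                block[at : at + w] = site
            seq.extend(block)
            pos += PROMOTER
            tss[gene] = pos  # first base after the promoter block
            genes.append((gene, cat))
            seq.append(rng.choice(list("ACGT")))  # 1-base "gene body"
            pos += 1
    return "".join(seq), tss, genes


if __name__ == "__main__":
    rng = np.random.default_rng(SEED)
    cats = {c: GENES_PER_CATEGORY for c in PLANT_PROBABILITY}
    chrom, tss, genes = synthetic_chromosome(rng, cats)
    genome = {"chrS": chrom}

    hits = []
    for gene, _ in genes:
        promoter, _ = extract_promoter(genome, "chrS", tss[gene], "+", PROMOTER)
        hits.extend(scan_promoter(gene, promoter, INR, p_cutoff=1e-4))

    gene_sets = {c: {g for g, gc in genes if gc == c} for c in cats}
    enrich = occurrence_enrichment(hits, gene_sets)
    enrich.to_csv(RESULTS / "motif_enrichment.tsv", sep="\t", index=False)
    profile = tss_positional_profile(hits, gene_sets, bin_width=50)
    profile.to_csv(RESULTS / "inr_profile.tsv", sep="\t", index=False)

    by_cat = enrich.set_index("category")
    print(f"{len(hits)} Inr hits at p <= 1e-4 across {len(genes)} promoters")
    for cat in ("high", "medium", "low", "maternal"):
        row = by_cat.loc[cat]
        print(f"  {cat:8s} occurrence {row.proportion:.2f} "
              f"[{row.ci_low:.2f}, {row.ci_high:.2f}]")
    print(f"chi-square p = {enrich.p_value.iloc[0]:.2e} "
          f"(BH-adjusted {enrich.p_adjusted.iloc[0]:.2e})")
    peaks = profile.groupby("category")["peak_bin_start"].first()
    print("peak bin (offset from TSS):", dict(peaks))
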