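"""Compare smFISH-derived rates with scRNA-seq-derived rates.

For every high/medium cohort gene, the OLS slope of spot counts over
nuclei-staged time in the onset cell is compared with the calibrated
AC/min from the expression matrix: Pearson correlation and the fraction of
genes within a 2-fold band.  Writes results/concordance.tsv.
"""

import pandas as pd

import lineage_rates as lr
from lineage_rates.smfish import comparisons_frame

from common import RESULTS, ensure_fixtures

if __name__ == "__main__":
    fixtures = ensure_fixtures()
    tree = lr.load_lineage(fixtures / "lineage.tsv")
    timing = lr.default_timing()
    expr = lr.ExpressionMatrix(pd.read_csv(fixtures / "expr.tsv", sep="\t", index_col=0))
    fishobs = pd.read_csv(fixtures / "fish.tsv", sep="\t")
    truth = pd.read_csv(fixtures / "truth.tsv", sep="\t", index_col=0)

    records = lr.build_rate_table(expr, tree)
    by_edge = {(r.gene, r.daughter_cell): r for r in records}

    comps = []
    keep = truth[truth.designed_category.isin(["high", "medium"])]
    for gene, row in keep.iterrows():
        node = tree[row.onset_cell]
        lo = timing.time_to_nuclei(node.birth_time + 0.51)
        hi = timing.time_to_nuclei(node.birth_time + node.cycle_duration - 0.51)
        rate_fish = lr.smfish_rate(
            fishobs[fishobs.gene == gene], timing, (lo, hi), tree
        )
        comps.append(
            lr.RateComparison(gene, rate_fish, by_edge[(gene, row.onset_cell)].rate_per_min)
        )
    comparisons_frame(comps).to_csv(RESULTS / "concordance.tsv", sep="\t", index=False)

    out = lr.method_concordance(comps)
    print(f"{out['n']} genes compared: Pearson r = {out['pearson_r']:.2f}, "
          f"{100 * out['within_2fold_fraction']:.0f}% within 2-fold")
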