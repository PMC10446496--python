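"""Generate the synthetic embryo dataset used by the downstream analyses.

Simulates a 2,100-gene transcriptome (2,000-gene maternal background plus
the 100-gene zygotic cohort) on the bundled lineage with binomial division
partitioning, then renders a depth-1e6 scRNA-seq TPM matrix, smFISH spot
counts and a whole-embryo decay time course into results/fixtures/.
"""

from common import FIXTURES, ensure_fixtures

if __name__ == "__main__":
    ensure_fixtures()
    files = sorted(p.name for p in FIXTURES.glob("*.tsv"))
    print(f"fixtures in {FIXTURES}:")
    for f in files:
        print(f"  {f}")
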