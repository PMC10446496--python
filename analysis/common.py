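"""Shared paths and fixture bootstrap for the numbered analysis scripts."""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
FIXTURES = RESULTS / "fixtures"

SEED = 17


def ensure_fixtures() -> Path:
    """Write the synthetic input set if it is not already on disk."""
    if not (FIXTURES / "expr.tsv").exists():
        from click.testing import CliRunner

        from lineage_rates.cli import main

        FIXTURES.mkdir(parents=True, exist_ok=True)
        res = CliRunner().invoke(
            main, ["simulate", "--seed", str(SEED), "--out-dir", str(FIXTURES)]
        )
        if res.exit_code != 0:
            raise RuntimeError(res.output)
    return FIXTURES
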