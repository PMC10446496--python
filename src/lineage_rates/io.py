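"""Readers for the expression-matrix input formats.

Expression comes either as a plain TSV (gene rows × named-cell columns,
TPM) or as a MatrixMarket triplet with separate row/column name files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io

from .rates import ExpressionMatrix


def load_expression(
    path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix from TSV or MatrixMarket (.mtx).

    For .mtx input, ``genes_path`` and ``cells_path`` are required
    one-name-per-line files for the rows and columns.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MatrixMarket input needs gene and cell name files")
        mat = scipy.io.mmread(path).toarray()
        genes = Path(genes_path).read_text().split()
        cells = Path(cells_path).read_text().split()
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(genes)} genes × {len(cells)} cells"
            )
        df = pd.DataFrame(mat, index=genes, columns=cells)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, unit="TPM")
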