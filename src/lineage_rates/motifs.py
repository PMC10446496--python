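"""Position-weight-matrix scanning of promoter sequences.

Promoter motifs (core elements such as the Initiator, and lineage-specific
transcription-factor sites) are scored as log-odds against a 0-order
background at every offset of both strands.  Statistical significance per
match is the exact p-value of its score under the background model,
computed by dynamic-programming convolution of the per-position score
distributions — the same null FIMO uses — and matches with p ≤ cutoff
(default 1e-4) are reported.  Windows containing N are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PWM", "MotifHit", "read_meme", "scan_pwm", "scan_promoter"]

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# exact dict-convolution of the null is kept for motifs whose worst-case
# state count (4^w) stays tractable; wider motifs merge states by rounding
_EXACT_WIDTH_LIMIT = 10
_COARSE_DECIMALS = 4


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One significant motif match; offset is relative to the TSS
    (negative = upstream) when produced by scan_promoter, otherwise the
    0-based start within the scanned sequence."""

    gene: str
    motif: str
    offset: int
    strand: str
    score: float
    p_value: float


@dataclass
class PWM:
    """Probability matrix (positions × ACGT) with a 0-order background.

    A pseudocount keeps all probabilities positive so log-odds are finite;
    rows are renormalised to sum to 1.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-4

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be positions × 4 (ACGT)")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("each PWM position must sum to 1")
        m = m + self.pseudocount
        self.matrix = m / m.sum(axis=1, keepdims=True)
        bg = np.asarray(self.background, dtype=float)
        self.background = bg / bg.sum()
        # log2 odds per position per base
        self.log_odds = np.log2(self.matrix / self.background)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def score(self, window: str) -> float:
        """Log-odds score of one window (length = width, ACGT only).

        Summed position by position in order, matching the convolution of
        the null distribution bit-for-bit.
        """
        if len(window) != self.width:
            raise ValueError("window length must equal motif width")
        s = 0.0
        for i, base in enumerate(window):
            s += self.log_odds[i, _INDEX[base]]
        return s

    def score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact null distribution of the score under the background.

        Returns (sorted unique scores, tail probabilities P(S ≥ score)).
        """
        exact = self.width <= _EXACT_WIDTH_LIMIT
        dist: dict[float, float] = {0.0: 1.0}
        for i in range(self.width):
            nxt: dict[float, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    key = s + self.log_odds[i, b]
                    if not exact:
                        key = round(key, _COARSE_DECIMALS)
                    nxt[key] = nxt.get(key, 0.0) + p * self.background[b]
            dist = nxt
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        tail = probs[::-1].cumsum()[::-1]
        return scores, tail

    def p_value_fn(self):
        """Callable score → exact one-sided p-value P(S ≥ score)."""
        scores, tail = self.score_distribution()

        def pval(s: float) -> float:
            # small slack absorbs float-noise below the granularity of the
            # log-odds table so equal scores get equal p-values
            idx = np.searchsorted(scores, s - 1e-9, side="left")
            if idx >= len(scores):
                return 0.0
            return float(tail[idx])

        return pval


def read_meme(path: str | Path) -> list[PWM]:
    """Parse PWMs from MEME minimal motif format."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    background = np.full(4, 0.25)
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.lower().startswith("background letter frequencies"):
            i += 1
            toks: list[str] = []
            while i < len(lines) and lines[i] and not lines[i].startswith("MOTIF"):
                toks.extend(lines[i].split())
                i += 1
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in ALPHABET])
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].startswith("letter-probability matrix"):
                i += 1
            header = lines[i]
            width = None
            toks = header.replace(":", " ").split()
            for j, tok in enumerate(toks):
                if tok == "w=":
                    width = int(toks[j + 1])
            i += 1
            rows = []
            while i < len(lines) and lines[i] and not lines[i].startswith("MOTIF"):
                parts = lines[i].split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
                    i += 1
                else:
                    break
            if width is not None and len(rows) != width:
                raise ValueError(f"motif {name}: expected {width} rows, found {len(rows)}")
            pwms.append(PWM(name=name, matrix=np.array(rows), background=background.copy()))
            continue
        i += 1
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def scan_pwm(
    sequence: str,
    pwm: PWM,
    p_cutoff: float = 1e-4,
    both_strands: bool = True,
    gene: str = "",
    tss_relative: bool = False,
) -> list[MotifHit]:
    """All significant matches of one PWM in one sequence.

    Scores every offset on the forward strand and (by default) the reverse
    complement; a hit's reported strand is the one whose window matched.
    With ``tss_relative`` the offset is start − len(sequence), so a
    promoter ending at the TSS yields offsets in [−len, −width].
    """
    seq = sequence.upper()
    w = pwm.width
    if len(seq) < w:
        return []
    pval = pwm.p_value_fn()
    hits: list[MotifHit] = []
    shift = -len(seq) if tss_relative else 0
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w]
        if any(b not in _INDEX for b in window):
            continue
        strands = [("+", window)]
        if both_strands:
            strands.append(("-", reverse_complement(window)))
        for strand, win in strands:
            s = pwm.score(win)
            p = pval(s)
            if p <= p_cutoff:
                hits.append(
                    MotifHit(
                        gene=gene,
                        motif=pwm.name,
                        offset=start + shift,
                        strand=strand,
                        score=s,
                        p_value=p,
                    )
                )
    return hits


def scan_promoter(
    gene: str, promoter_seq: str, pwm: PWM, p_cutoff: float = 1e-4
) -> list[MotifHit]:
    """Scan one promoter (sequence ends at the TSS); offsets are TSS-relative."""
    return scan_pwm(
        promoter_seq, pwm, p_cutoff=p_cutoff, gene=gene, tss_relative=True
    )
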