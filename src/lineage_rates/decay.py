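"""mRNA decay kinetics and decay-adjusted synthesis rates.

Raw accumulation rates understate synthesis whenever transcripts also turn
over during the cell cycle.  This module (i) fits per-gene half-lives from
whole-embryo time-course expression by a one-phase exponential decay fit on
the window from peak abundance to the first zero, and (ii) inverts the
constant-synthesis / first-order-decay model

    dA/dt = k − λA,   A(t) = A0·e^(−λt) + (k/λ)(1 − e^(−λt)),  λ = ln2 / t½

for the synthesis rate k given the transcripts inherited at birth (A0), the
transcripts at division (A_T) and the cycle length.  As λ → 0 the estimate
reduces continuously to the raw rate (A_T − A0)/t.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .lineage import LineageTree
from .rates import RateRecord

__all__ = [
    "DecayFit",
    "SynthesisEstimate",
    "fit_half_life",
    "fit_timecourse",
    "synthesis_rate",
    "adjust_rate_table",
]

log = logging.getLogger(__name__)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DecayFit:
    """One-phase decay fit for one gene: A(t) = A_peak·e^(−λ(t−t_peak))."""

    gene: str
    half_life: float  # minutes
    lam: float  # per-minute decay rate, ln2 / half_life
    n_points: int
    rss: float

    def __post_init__(self):
        if abs(self.lam * self.half_life - LN2) > 1e-9:
            raise ValueError("lambda and half_life are inconsistent")


@dataclass(frozen=True)
class SynthesisEstimate:
    """Decay-adjusted synthesis rate for one gene on one lineage edge."""

    gene: str
    daughter_cell: str
    k: float  # transcripts/min
    raw_rate: float  # AC / cycle, transcripts/min
    adjustment_fold: float  # k / raw_rate
    adjusted: bool  # False when no half-life fit was available


def _decay_window(times: np.ndarray, abund: np.ndarray, min_points: int):
    """Points from the abundance maximum to the first zero (inclusive).

    Zeros after the first carry no decay information (the log initializer
    is undefined there) and are excluded.
    """
    peak = int(np.argmax(abund))
    t = times[peak:]
    a = abund[peak:]
    zeros = np.nonzero(a == 0)[0]
    if zeros.size:
        t = t[: zeros[0] + 1]
        a = a[: zeros[0] + 1]
    if len(t) < min_points:
        return None
    return t, a


def fit_half_life(
    times: np.ndarray | list[float],
    abundances: np.ndarray | list[float],
    min_points: int = 3,
    gene: str = "",
) -> DecayFit | None:
    """One-phase decay fit on the falling limb of a time course.

    Restricts to the window from maximum abundance to the first zero, then
    fits A(t) = A_peak·e^(−λ(t−t_peak)) by nonlinear least squares on the
    linear scale, initialised by log-linear regression on the positive
    points.  Returns None (insufficient data) when the window has fewer
    than ``min_points`` points, when abundance is identically zero, or when
    the fitted λ is not positive (abundance not decaying).
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(abundances, dtype=float)
    if t.shape != a.shape:
        raise ValueError("times and abundances must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    if not a.any():
        return None
    window = _decay_window(t, a, min_points)
    if window is None:
        return None
    tw, aw = window
    t0 = tw[0]
    pos = aw > 0
    if pos.sum() < 2:
        return None
    # log-linear initializer on positive points
    slope, intercept = np.polyfit(tw[pos] - t0, np.log(aw[pos]), 1)
    if slope >= 0:
        return None
    try:
        import warnings

        with warnings.catch_warnings():
            # exactly-determined fits (2 points, 2 params) cannot estimate a
            # covariance; the estimate itself is still exact
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                lambda x, a0, lam: a0 * np.exp(-lam * x),
                tw - t0,
                aw,
                p0=(math.exp(intercept), -slope),
                maxfev=10_000,
            )
    except RuntimeError:
        return None
    a0_hat, lam = popt
    if lam <= 0 or not np.isfinite(lam):
        return None
    resid = aw - a0_hat * np.exp(-lam * (tw - t0))
    return DecayFit(
        gene=gene,
        half_life=LN2 / lam,
        lam=lam,
        n_points=int(len(tw)),
        rss=float(resid @ resid),
    )


def fit_timecourse(
    timecourse: pd.DataFrame, min_points: int = 3
) -> dict[str, DecayFit]:
    """Fit every gene column of a time course (index or column 'time_min')."""
    df = timecourse
    if "time_min" in df.columns:
        df = df.set_index("time_min")
    t = df.index.to_numpy(dtype=float)
    fits: dict[str, DecayFit] = {}
    for gene in df.columns:
        fit = fit_half_life(t, df[gene].to_numpy(dtype=float), min_points, gene=gene)
        if fit is not None:
            fits[gene] = fit
    return fits


def synthesis_rate(a0: float, a_t: float, t: float, half_life: float) -> float:
    """Synthesis rate k from abundances at birth (a0) and division (a_t).

    Solves A_T = A0·e^(−λt) + (k/λ)(1 − e^(−λt)) for k:

        k = λ (A_T − A0·e^(−λt)) / (1 − e^(−λt))

    Computed with expm1 for numerical continuity; at λt below 1e-8 the
    no-decay limit (A_T − A0)/t is returned directly (the two branches
    differ by less than λ·(A_T + A0)/2 there).
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if half_life <= 0:
        raise ValueError("half-life must be positive")
    if a0 < 0 or a_t < 0:
        raise ValueError("abundances must be non-negative")
    lam = LN2 / half_life
    x = lam * t
    if x < 1e-8:
        return (a_t - a0) / t
    denom = -math.expm1(-x)  # 1 − e^(−λt), accurate for small x
    return lam * (a_t - a0 * math.exp(-x)) / denom


def adjust_rate_table(
    records: Iterable[RateRecord],
    fits: Mapping[str, DecayFit],
    tree: LineageTree,
    expr_tpm: pd.DataFrame | None = None,
    embryo_total: float = 8_000_000.0,
) -> list[SynthesisEstimate]:
    """Decay-adjusted synthesis rate per rate record.

    A0 is the inherited count (parent TPM calibrated at the daughter's
    volume) and A_T the daughter count over the daughter's cycle.  When
    ``expr_tpm`` is omitted the counts are reconstructed from the record's
    AC assuming A0 = 0 (valid for newly activated genes).  Genes without a
    decay fit keep their raw rate, flagged unadjusted.
    """
    out: list[SynthesisEstimate] = []
    for r in records:
        cyc = tree.cycle_duration(r.daughter_cell)
        raw = r.ac / cyc
        fit = fits.get(r.gene)
        if fit is None:
            out.append(
                SynthesisEstimate(r.gene, r.daughter_cell, raw, raw, 1.0, adjusted=False)
            )
            continue
        vol_d = tree.volume_fraction(r.daughter_cell)
        if expr_tpm is not None:
            a0 = float(expr_tpm.loc[r.gene, r.parent_cell]) / 1e6 * vol_d * embryo_total
            a_t = a0 + r.ac
        else:
            a0 = 0.0
            a_t = max(r.ac, 0.0)
        if a_t <= a0:  # no net accumulation: decay adjustment is undefined
            out.append(
                SynthesisEstimate(r.gene, r.daughter_cell, raw, raw, 1.0, adjusted=False)
            )
            continue
        k = synthesis_rate(a0, a_t, cyc, fit.half_life)
        fold = k / raw if raw > 0 else float("nan")
        out.append(SynthesisEstimate(r.gene, r.daughter_cell, k, raw, fold, adjusted=True))
    return out


def decay_fits_frame(fits: Mapping[str, DecayFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": f.gene,
                "t_half_min": f.half_life,
                "lambda": f.lam,
                "n_points": f.n_points,
                "rss": f.rss,
            }
            for f in fits.values()
        ]
    )


def synthesis_frame(estimates: Iterable[SynthesisEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": e.gene,
                "daughter": e.daughter_cell,
                "k_per_min": e.k,
                "raw_rate_per_min": e.raw_rate,
                "adjustment_fold": e.adjustment_fold,
                "adjusted": e.adjusted,
            }
            for e in estimates
        ]
    )
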