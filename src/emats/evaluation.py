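"""Mel-cepstral distortion and report statistics.

MCD between a reference and a generated cepstral sequence (13 retained
coefficients, energy coefficient excluded) is

    MCD = (1/T) Σ_m (10 / ln 10) · sqrt( 2 Σ_{d=1..13} (C_{m,d} − Ĉ_{m,d})² )

in dB, averaged over the T frames so that values are length-independent.
Lower is better.  Group comparisons use the exact Mann–Whitney U test
(mid-ranks for ties, full enumeration of group assignments — appropriate at
n = 8 speakers per condition); association uses the Pearson product-moment
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .features import MFCC_KEEP

MCD_CONST = 10.0 / np.log(10.0)


def mcd(reference: np.ndarray, generated: np.ndarray) -> float:
    """Frame-averaged mel-cepstral distortion (dB) between two (T, 13) sequences."""
    ref = np.atleast_2d(np.asarray(reference, dtype=np.float64))
    gen = np.atleast_2d(np.asarray(generated, dtype=np.float64))
    if ref.shape != gen.shape:
        raise ValueError(f"sequence shapes differ: {ref.shape} vs {gen.shape}")
    if ref.shape[1] != MFCC_KEEP:
        raise ValueError(f"expected {MFCC_KEEP} cepstral coefficients, got {ref.shape[1]}")
    per_frame = MCD_CONST * np.sqrt(2.0 * np.sum((ref - gen) ** 2, axis=1))
    return float(per_frame.mean())


def aggregate(report: pd.DataFrame) -> pd.DataFrame:
    """Append ``Mean`` and ``STD`` (sample, n−1) rows to a per-speaker table."""
    if report.empty:
        raise ValueError("cannot aggregate an empty report")
    out = report.copy()
    out.loc["Mean"] = report.mean()
    out.loc["STD"] = report.std(ddof=1)
    return out


# ---------------------------------------------------------------------------
# Mann–Whitney U (exact, mid-ranks)
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a: #(a > b) pairs + half the ties."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(group_a, group_b, max_exact: int = 12) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney U test.

    Returns ``(U, p)`` where U is the larger of the two samples' U statistics
    and p is the exact two-sided probability obtained by enumerating all
    C(n_a + n_b, n_a) assignments of the pooled values to groups (mid-ranks
    under ties).  Falls back to the normal approximation when both groups
    exceed ``max_exact``.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_a = _u_statistic(a, b)
    u_b = a.size * b.size - u_a
    u_max = max(u_a, u_b)
    if min(a.size, b.size) > max_exact or comb(a.size + b.size, a.size) > 500_000:
        res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return u_max, float(res.pvalue)
    pooled = np.concatenate([a, b])
    n = pooled.size
    count_extreme = 0
    total = 0
    lo = min(u_a, u_b)
    for idx in combinations(range(n), a.size):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u >= u_max or u <= lo:
            count_extreme += 1
    return u_max, count_extreme / total


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    return float(_sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def vc_matrix_report(pairwise: pd.DataFrame) -> pd.DataFrame:
    """Validate a source × target VC-MCD matrix and append column averages.

    The diagonal must be empty (NaN): converting a speaker to themselves is
    not applicable.  The ``Average`` row holds per-target means over the
    off-diagonal source speakers.
    """
    if pairwise.shape[0] != pairwise.shape[1]:
        raise ValueError("pairwise VC matrix must be square")
    if list(pairwise.index) != list(pairwise.columns):
        raise ValueError("row and column speaker orders must match")
    diag = np.diag(pairwise.to_numpy(dtype=np.float64))
    if not np.isnan(diag).all():
        raise ValueError("diagonal cells must be empty (self-conversion undefined)")
    out = pairwise.copy()
    out.loc["Average"] = pairwise.mean(axis=0, skipna=True)
    return out


@dataclass
class EvaluationReport:
    """Per-speaker, per-design MCD matrix plus optional pairwise VC matrix."""

    mcd_table: pd.DataFrame
    vc_table: pd.DataFrame | None = None

    def with_aggregates(self) -> pd.DataFrame:
        return aggregate(self.mcd_table)

    def design_means(self) -> pd.Series:
        return self.mcd_table.mean()

    def to_csv(self, path) -> None:
        self.with_aggregates().to_csv(path, float_format="%.4f")
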