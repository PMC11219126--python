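"""Temporal autocorrelation of filtered gaze signals.

Low-pass filtering necessarily increases temporal autocorrelation; this
module quantifies the effect.  Per-block autocorrelations out to lag 5
are Fisher-Z transformed (atanh) before testing, condition differences
are assessed with the Friedman repeated-measures rank test, and pairwise
follow-ups compare mean within-block ranks against studentized-range
critical values (the Nemenyi construction, which mirrors the behaviour
of MATLAB's ``multcompare`` after ``friedman``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AcfTable",
    "FriedmanResult",
    "PairwiseComparison",
    "acf",
    "fisher_z",
    "inverse_fisher_z",
    "lag1_significance",
    "friedman_across_conditions",
    "pairwise_rank_comparisons",
]


def acf(block: np.ndarray, n_lags: int = 5) -> np.ndarray:
    """Sample autocorrelation at lags 1..n_lags, biased normalisation.

    r[k] = sum_t d[t] d[t+k] / sum_t d[t]^2 with d the mean-removed
    block; the implicit lag-0 value is exactly 1 and |r| <= 1.
    """
    x = np.asarray(block, dtype=float)
    if len(x) <= n_lags + 2:
        raise ValueError("block too short for the requested number of lags")
    d = x - x.mean()
    den = float(d @ d)
    scale = max(1.0, float(np.abs(x).max()))
    if den <= len(x) * (1e-12 * scale) ** 2:
        raise ValueError("ACF undefined for a (near-)constant block")
    return np.array([float(d[:-k] @ d[k:]) / den for k in range(1, n_lags + 1)])


def fisher_z(r):
    """Fisher-Z transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher-Z requires |r| < 1")
    return np.arctanh(r)


def inverse_fisher_z(z):
    """Inverse Fisher-Z transform, r = tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


def lag1_significance(r1: float, n: int) -> float:
    """Two-sided normal test of a lag-1 autocorrelation.

    Uses the Fisher-Z statistic z*sqrt(n-3), whose null distribution is
    approximately standard normal for block length n.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    stat = np.arctanh(r1) * np.sqrt(n - 3)
    return float(2.0 * stats.norm.sf(abs(stat)))


@dataclass
class AcfTable:
    """Per-block, per-condition autocorrelations at lags 1..n_lags."""

    conditions: list
    r: np.ndarray                 # (n_blocks, n_conditions, n_lags)
    z: np.ndarray = field(default=None)
    block_len: int = 0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 3 or self.r.shape[1] != len(self.conditions):
            raise ValueError("r must be (n_blocks, n_conditions, n_lags)")
        if self.z is None:
            self.z = fisher_z(self.r)

    @property
    def n_blocks(self) -> int:
        return self.r.shape[0]

    @property
    def n_lags(self) -> int:
        return self.r.shape[2]

    @classmethod
    def from_blocks(cls, blocks_by_condition: dict, n_lags: int = 5) -> "AcfTable":
        """Build the table from equal-length block lists per condition."""
        conditions = list(blocks_by_condition)
        counts = {len(blocks_by_condition[c]) for c in conditions}
        if len(counts) != 1:
            raise ValueError("all conditions need the same number of blocks")
        (n_blocks,) = counts
        if n_blocks == 0:
            raise ValueError("need at least one block")
        block_len = len(blocks_by_condition[conditions[0]][0])
        r = np.empty((n_blocks, len(conditions), n_lags))
        for j, c in enumerate(conditions):
            for i, blk in enumerate(blocks_by_condition[c]):
                r[i, j] = acf(blk, n_lags)
        return cls(conditions=conditions, r=r, block_len=block_len)

    def z_at_lag(self, lag: int) -> np.ndarray:
        """(n_blocks, n_conditions) Fisher-Z values at one lag (1-based)."""
        if not 1 <= lag <= self.n_lags:
            raise ValueError(f"lag must be in 1..{self.n_lags}")
        return self.z[:, :, lag - 1]

    def to_csv(self, path) -> None:
        rows = []
        for i in range(self.n_blocks):
            for j, c in enumerate(self.conditions):
                row = {"block": i, "condition": c}
                for k in range(self.n_lags):
                    row[f"r_lag{k+1}"] = self.r[i, j, k]
                    row[f"z_lag{k+1}"] = self.z[i, j, k]
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


@dataclass
class PairwiseComparison:
    condition_a: str
    condition_b: str
    rank_difference: float   # mean within-block rank of a minus that of b
    z_difference: float      # mean Fisher-Z of a minus that of b
    p_adjusted: float
    significant: bool


@dataclass
class FriedmanResult:
    lag: int
    chi2: float
    df: int
    p: float
    mean_ranks: dict
    pairwise: list

    def pairwise_to_csv(self, path) -> None:
        rows = [{"condition_a": c.condition_a, "condition_b": c.condition_b,
                 "rank_difference": c.rank_difference,
                 "z_difference": c.z_difference,
                 "p_adjusted": c.p_adjusted,
                 "significant": c.significant} for c in self.pairwise]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def _within_block_ranks(data: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, data)  # average-rank ties


def pairwise_rank_comparisons(table: AcfTable, lag: int,
                              alpha: float = 0.05) -> list:
    """All C(k,2) pairwise comparisons on mean within-block ranks.

    The statistic |R_i - R_j| / sqrt(k(k+1)/(12 n)) is referred to the
    studentized-range distribution with k groups and infinite degrees of
    freedom (Tukey-HSD-style control over the family of comparisons).
    """
    data = table.z_at_lag(lag)
    n, k = data.shape
    ranks = _within_block_ranks(data)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = mean_ranks[i] - mean_ranks[j]
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, np.inf))
            p = min(1.0, max(0.0, p))
            out.append(PairwiseComparison(
                condition_a=table.conditions[i],
                condition_b=table.conditions[j],
                rank_difference=float(diff),
                z_difference=float(data[:, i].mean() - data[:, j].mean()),
                p_adjusted=p,
                significant=p < alpha))
    return out


def friedman_across_conditions(table: AcfTable, lag: int,
                               alpha: float = 0.05) -> FriedmanResult:
    """Friedman chi-square across conditions at one lag, with follow-ups.

    Ties are handled with average ranks and the usual tie correction.
    A table in which every block is constant across conditions carries
    no evidence of an effect: chi2 = 0, p = 1.
    """
    data = table.z_at_lag(lag)
    n, k = data.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 conditions and 2 blocks")
    if not np.all(np.isfinite(data)):
        raise ValueError("incomplete table: non-finite Fisher-Z entries")
    if np.all(data == data[:, :1]):
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*(data[:, j] for j in range(k)))
    ranks_mean = _within_block_ranks(data).mean(axis=0)
    return FriedmanResult(
        lag=lag, chi2=float(chi2), df=k - 1, p=float(p),
        mean_ranks={c: float(m) for c, m in zip(table.conditions, ranks_mean)},
        pairwise=pairwise_rank_comparisons(table, lag, alpha=alpha))
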