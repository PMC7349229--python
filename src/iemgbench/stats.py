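"""Nonparametric comparisons across schemes, days and sessions.

The Friedman test ranks the treatments within each block (mid-ranks on
ties), forms the chi-square statistic with the standard tie correction and
refers it to a chi-square distribution with k - 1 degrees of freedom.  The
post-hoc procedure is Bonferroni-corrected pairwise Wilcoxon signed-rank
tests at a family-wise alpha of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class RankTable:
    """Blocks x treatments matrix of one metric (no missing cells)."""

    blocks: tuple
    treatments: tuple
    values: np.ndarray

    def __post_init__(self):
        self.blocks = tuple(self.blocks)
        self.treatments = tuple(self.treatments)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.blocks), len(self.treatments)):
            raise ValueError(
                f"values must be (n_blocks, n_treatments) = "
                f"{(len(self.blocks), len(self.treatments))}, got {self.values.shape}"
            )
        if len(self.blocks) < 2 or len(self.treatments) < 2:
            raise ValueError("need at least 2 blocks and 2 treatments")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rank table must not contain missing values")


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    p_value: float


def friedman_statistic(values: np.ndarray) -> tuple[float, int]:
    """Tie-corrected Friedman chi-square statistic and its df.

    Conover's form: with within-block mid-ranks R_ij, column sums R_j,
    A = sum R_ij^2 and C = n k (k+1)^2 / 4,

        Q = (k - 1) * sum_j (R_j - n (k+1)/2)^2 / (A - C).

    Without ties A - C reduces to n k (k^2 - 1) / 12 and Q is the textbook
    12/(n k (k+1)) sum R_j^2 - 3 n (k+1).  Completely tied tables give Q = 0.
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = sps.rankdata(values, axis=1)  # mid-ranks on ties
    col_sums = ranks.sum(axis=0)
    a = float(np.sum(ranks**2))
    c = n * k * (k + 1) ** 2 / 4.0
    denom = a - c
    if denom <= 0:  # every block completely tied
        return 0.0, k - 1
    q = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2)) / denom
    return q, k - 1


def friedman_test(table: RankTable) -> FriedmanResult:
    """Friedman two-way rank test over the table's blocks and treatments."""
    q, df = friedman_statistic(table.values)
    return FriedmanResult(statistic=q, df=df, p_value=float(sps.chi2.sf(q, df)))


@dataclass
class PairwiseComparison:
    treatment_a: str
    treatment_b: str
    p_raw: float
    p_adjusted: float
    significant: bool


def pairwise_posthoc(table: RankTable, alpha: float = 0.05) -> list[PairwiseComparison]:
    """Bonferroni-corrected pairwise Wilcoxon signed-rank comparisons."""
    k = len(table.treatments)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    out = []
    for i, j in pairs:
        diff = table.values[:, i] - table.values[:, j]
        if np.all(diff == 0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(table.values[:, i], table.values[:, j]).pvalue)
        p_adj = min(1.0, p * m)
        out.append(
            PairwiseComparison(
                treatment_a=str(table.treatments[i]),
                treatment_b=str(table.treatments[j]),
                p_raw=p,
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    return out
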