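"""Exact and rank-based group-comparison statistics.

The centrepiece is an exact Fisher test of independence for general r x c
contingency tables: under the null, tables with the observed margins follow
the multivariate hypergeometric distribution, and the two-sided p-value is
the total probability of all tables in the fixed-margin fibre whose
probability does not exceed that of the observed table (probability-mass
ordering, the convention shared by R's ``fisher.test``). The fibre is
enumerated recursively row by row under the remaining column margins,
which is comfortably feasible at the cohort sizes this test is used for
(n below a few hundred for 3 x 2 tables).

Rank-based comparisons (Kruskal-Wallis, pairwise Wilcoxon rank-sum) and
the Benjamini-Hochberg step-up FDR adjustment wrap scipy / statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

_TIE_EPS = 1e-12  # relative slack so probability ties count into the tail


@dataclass
class PvalueSet:
    labels: list[str]
    raw: np.ndarray
    adjusted: np.ndarray

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        self.adjusted = np.asarray(self.adjusted, dtype=float)
        if np.any((self.raw < 0) | (self.raw > 1)) or np.any(
            (self.adjusted < 0) | (self.adjusted > 1 + 1e-12)
        ):
            raise ValueError("p-values must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            lab: {"p": float(p), "p_adj": float(q)}
            for lab, p, q in zip(self.labels, self.raw, self.adjusted)
        }


def _validate_table(table) -> np.ndarray:
    tab = np.asarray(table, dtype=np.int64)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    return tab


def enumerate_tables(row_margins, col_margins):
    """Yield every non-negative integer table with the given margins.

    Row-by-row recursive generation constrained by the remaining column
    margins (the fixed-margin fibre of the observed table).
    """
    rows = [int(x) for x in row_margins]
    cols = [int(x) for x in col_margins]
    if sum(rows) != sum(cols):
        raise ValueError("row and column margins must have equal totals")
    r, c = len(rows), len(cols)
    tab = np.zeros((r, c), dtype=np.int64)

    def fill_row(row_idx: int, col_rem: list[int]):
        if row_idx == r - 1:
            if all(v >= 0 for v in col_rem):
                tab[-1] = col_rem
                yield tab.copy()
            return

        target = rows[row_idx]

        def fill_cell(j: int, rem: int, col_rem_: list[int]):
            if j == c - 1:
                if rem <= col_rem_[j]:
                    tab[row_idx, j] = rem
                    nxt = list(col_rem_)
                    nxt[j] -= rem
                    yield from fill_row(row_idx + 1, nxt)
                return
            for v in range(min(rem, col_rem_[j]) + 1):
                tab[row_idx, j] = v
                nxt = list(col_rem_)
                nxt[j] -= v
                yield from fill_cell(j + 1, rem - v, nxt)

        yield from fill_cell(0, target, col_rem)

    yield from fill_row(0, cols)


def fisher_exact(table) -> float:
    """Two-sided exact test of independence for an r x c table.

    Returns the p-value. Degenerate tables (any zero row or column
    margin) return 1.0.
    """
    tab = _validate_table(table)
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        return 1.0
    n = int(tab.sum())

    log_const = gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum() - gammaln(n + 1.0)
    logp_obs = log_const - gammaln(tab + 1.0).sum()
    cut = logp_obs + np.log1p(_TIE_EPS)

    total = 0.0
    for cand in enumerate_tables(rows, cols):
        logp = log_const - gammaln(cand + 1.0).sum()
        if logp <= cut:
            total += np.exp(logp)
    return float(min(total, 1.0))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR-adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pairwise_fisher_bh(table, row_labels=None) -> PvalueSet:
    """2 x 2 Fisher tests for every row pair, BH-adjusted over all pairs."""
    tab = _validate_table(table)
    r = tab.shape[0]
    if r < 3:
        raise ValueError("pairwise comparisons need at least 3 rows")
    if row_labels is None:
        row_labels = [str(i) for i in range(r)]
    labels, raw = [], []
    for i in range(r):
        for j in range(i + 1, r):
            labels.append(f"{row_labels[i]} vs {row_labels[j]}")
            raw.append(fisher_exact(tab[[i, j], :]))
    raw = np.array(raw)
    return PvalueSet(labels, raw, benjamini_hochberg(raw))


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Kruskal-Wallis rank sum test -> (H with tie correction, df, p).

    The p-value uses the chi-squared approximation with k-1 degrees of
    freedom. All observations identical gives the degenerate (H=0, p=1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), df, float(p)


def _rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if max(x.size, y.size) <= 25 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def pairwise_wilcoxon_bh(groups, labels=None) -> PvalueSet:
    """Pairwise Wilcoxon rank-sum tests over groups, BH-adjusted."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    labs, raw = [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            labs.append(f"{labels[i]} vs {labels[j]}")
            xi, yj = groups[i], groups[j]
            if np.array_equal(np.sort(xi), np.sort(yj)):
                raw.append(1.0)
            else:
                raw.append(_rank_sum_p(xi, yj))
    raw = np.array(raw)
    return PvalueSet(labs, raw, benjamini_hochberg(raw))
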