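"""Sample-level expression statistics.

Raw expression of a protein in a sample is the sum of its molecule counts
over all single EVs. Between-sample normalization uses the trimmed mean of
M-values (TMM); two-group differential testing follows an adaptive tree:
Shapiro-Wilk normality per group, then an F-test of variance homogeneity,
selecting Student's t, Welch's t, or the Mann-Whitney U test, with
Benjamini-Hochberg correction across the panel.

TMM, the test-selection tree, Mann-Whitney (exact for small groups,
tie-corrected normal approximation otherwise) and BH are implemented here;
Shapiro-Wilk, F and t p-values come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import SingleEVMatrix


@dataclass
class ExpressionSet:
    """Protein x sample raw count table with group labels and TMM factors.

    ``normalized`` scales each sample by its effective library size
    (library size x TMM factor) to counts per million.
    """

    counts: pd.DataFrame          # proteins x samples, raw summed counts
    groups: pd.Series             # sample -> group label
    norm_factors: pd.Series | None = None

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def normalized(self) -> pd.DataFrame:
        if self.norm_factors is None:
            raise ValueError("call tmm_normalize first")
        eff = self.lib_sizes * self.norm_factors
        return self.counts / eff * 1e6


def aggregate(matrices: dict[str, SingleEVMatrix],
              groups: pd.Series) -> ExpressionSet:
    """Sum each sample's single-EV counts into per-protein totals."""
    panels = {tuple(m.proteins) for m in matrices.values()}
    if len(panels) != 1:
        raise ValueError("samples use different panels")
    counts = pd.DataFrame({sid: m.protein_totals()
                           for sid, m in matrices.items()})
    return ExpressionSet(counts, groups.loc[counts.columns])


# ----------------------------------------------------------------- TMM ----
def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     trim_M: float, trim_A: float) -> float:
    """TMM factor of one sample against the reference (canonical recipe:
    precision-weighted mean of log2 ratios after trimming trim_M of each
    M tail and trim_A of each A tail)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    logR = np.log2((o / n_obs) / (r / n_ref))
    absE = 0.5 * (np.log2(o / n_obs) + np.log2(r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)  # asymptotic var
    n = logR.size
    if n == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    loL = math.floor(n * trim_M) + 1
    hiL = n + 1 - loL
    loS = math.floor(n * trim_A) + 1
    hiS = n + 1 - loS
    rank_M = stats.rankdata(logR)
    rank_A = stats.rankdata(absE)
    sel = (rank_M >= loL) & (rank_M <= hiL) & (rank_A >= loS) & (rank_A <= hiS)
    if not sel.any():
        return 1.0
    # precision weighting: inverse-variance weighted mean of log ratios
    f = (logR[sel] / v[sel]).sum() / (1.0 / v[sel]).sum()
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return float(2.0 ** f)


def tmm_norm_factors(counts: pd.DataFrame, trim_M: float = 0.30,
                     trim_A: float = 0.05) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    Reference sample: the one whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction across samples.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    uq = np.quantile(X, 0.75, axis=0) / lib
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        _tmm_pair_factor(X[:, j], X[:, ref_j], trim_M, trim_A)
        for j in range(X.shape[1])])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def tmm_normalize(expr: ExpressionSet, trim_M: float = 0.30,
                  trim_A: float = 0.05) -> ExpressionSet:
    expr.norm_factors = tmm_norm_factors(expr.counts, trim_M, trim_A)
    return expr


# ------------------------------------------------------------ BH / MWU ----
def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (ties count 1/2), via midranks."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution (enumeration of all rank splits of the pooled
    midranks, so ties are handled) when both groups have at most
    ``exact_max_n`` observations; otherwise tie-corrected normal
    approximation with continuity correction.

    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        us = np.array([ranks[list(idx)].sum() - offset
                       for idx in combinations(range(n1 + n2), n1)])
        n_perm = us.size
        # convention of the exact two-sided test: double the smaller tail
        p = 2.0 * min((us <= u).sum(), (us >= u).sum()) / n_perm
        return u, min(p, 1.0)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    sd = math.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
    if sd == 0:
        return u, 1.0
    num = u - n1 * n2 / 2.0
    z = (num - 0.5 * np.sign(num)) / sd
    return u, float(2.0 * stats.norm.sf(abs(z)))


# ------------------------------------------------- differential testing ----
def _variance_f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F-test p-value for equality of variances."""
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        return 1.0
    if v2 == 0 or v1 == 0:
        return 0.0
    f = v1 / v2
    p = stats.f.cdf(f, x.size - 1, y.size - 1)
    return float(2.0 * min(p, 1.0 - p))


def select_test(normality_p1: float, normality_p2: float, variance_p: float,
                alpha: float = 0.05) -> str:
    """The adaptive test-selection tree: Mann-Whitney when either group
    fails normality, Welch's t when variances differ, Student's t
    otherwise."""
    if normality_p1 < alpha or normality_p2 < alpha:
        return "mann_whitney"
    if variance_p < alpha:
        return "welch_t"
    return "student_t"


def differential_test(expr: ExpressionSet, case_group: str,
                      control_group: str | None = None,
                      alpha_assumption: float = 0.05,
                      use_normalized: bool = True) -> pd.DataFrame:
    """Per-protein two-group differential expression.

    Returns a table with group means, the selected test, raw and
    BH-adjusted p-values, and the direction of change in the case group.
    Proteins constant within both groups are flagged (test_used
    "undefined") and excluded from the BH family.
    """
    groups = expr.groups
    if control_group is None:
        others = [g for g in groups.unique() if g != case_group]
        if len(others) != 1:
            raise ValueError("control_group required with >2 groups")
        control_group = others[0]
    case_ids = groups.index[groups == case_group]
    ctrl_ids = groups.index[groups == control_group]
    if len(case_ids) < 3 or len(ctrl_ids) < 3:
        raise ValueError("each group needs n >= 3")
    values = expr.normalized if use_normalized else expr.counts

    rows = []
    for protein in values.index:
        x = values.loc[protein, case_ids].to_numpy(dtype=float)
        y = values.loc[protein, ctrl_ids].to_numpy(dtype=float)
        row = {"protein": protein,
               "mean_case": x.mean(), "mean_control": y.mean(),
               "direction": "up" if x.mean() >= y.mean() else "down"}
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            row.update(test_used="undefined", p_value=np.nan,
                       normality_p_case=np.nan, normality_p_control=np.nan,
                       variance_p=np.nan)
            rows.append(row)
            continue
        # Shapiro-Wilk is undefined for constant vectors; a constant group
        # is maximally non-normal for the tree's purpose
        sw1 = stats.shapiro(x).pvalue if np.ptp(x) > 0 else 0.0
        sw2 = stats.shapiro(y).pvalue if np.ptp(y) > 0 else 0.0
        fp = _variance_f_test(x, y)
        test = select_test(sw1, sw2, fp, alpha_assumption)
        if test == "mann_whitney":
            _, p = mann_whitney(x, y)
        elif test == "welch_t":
            p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        else:
            p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        row.update(test_used=test, p_value=p, normality_p_case=sw1,
                   normality_p_control=sw2, variance_p=fp)
        rows.append(row)
    result = pd.DataFrame(rows).set_index("protein")
    testable = result.test_used != "undefined"
    result["q_value"] = np.nan
    result.loc[testable, "q_value"] = bh_adjust(
        result.loc[testable, "p_value"].to_numpy())
    return result
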