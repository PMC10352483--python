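"""Clinical statistics: IHC product scoring, ordinal association,
survival, and ELISA standard-curve readout.

The immunohistochemistry (IHC) score is staining intensity (0-3) times the
positive-cell percentage bin (1-4: 1-25%, 26-50%, 51-75%, 76-100%),
dichotomized low (0-4) / high (5-12). Expression category is associated
with ordinal clinicopathological variables via the tie-corrected Spearman
rank correlation (expression coded low < high, clinical categories
ascending; p from the t approximation). Survival uses the Kaplan-Meier
product-limit estimator and the log-rank test (via lifelines). The ELISA
helper fits a standard curve (linear in log concentration, or 4PL) and
inverts it for sample optical densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import optimize, stats


# ----------------------------------------------------------- IHC score ----
@dataclass(frozen=True)
class IHCScore:
    intensity: int        # 0 none, 1 weak, 2 moderate, 3 strong
    percentage_bin: int   # 1: 1-25%, 2: 26-50%, 3: 51-75%, 4: 76-100%
    final: int            # intensity x percentage_bin, 0-12
    category: str         # "low" (0-4) or "high" (5-12)


def ihc_score(intensity: int, percentage_bin: int) -> IHCScore:
    """Product score with low/high dichotomization at 4/5."""
    if intensity not in range(4):
        raise ValueError(f"intensity must be 0-3, got {intensity}")
    if percentage_bin not in range(1, 5):
        raise ValueError(f"percentage_bin must be 1-4, got {percentage_bin}")
    final = intensity * percentage_bin
    return IHCScore(intensity, percentage_bin, final,
                    "low" if final <= 4 else "high")


# ------------------------------------------------- ordinal association ----
def load_cdcp1_ihc_table() -> pd.DataFrame:
    """Bundled CDCP1 IHC high/low contingency counts against ordinal
    clinicopathological variables in the 79-patient ovarian-cancer tissue
    cohort (patients with a missing value are absent from that variable's
    block)."""
    with resources.files("evscope.data").joinpath(
            "cdcp1_ihc_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def spearman_ordinal(table: pd.DataFrame) -> tuple[float, float, int]:
    """Tie-corrected Spearman correlation of an expression-by-stage table.

    ``table`` has one row per ordinal clinical category (ascending order)
    with columns ``high`` and ``low``. The table is expanded to
    per-patient (clinical rank, expression rank) pairs with expression
    coded low=0 < high=1; midranks handle the massive ties; p is two-sided
    from t = rs sqrt(n-2)/sqrt(1-rs^2) on n-2 df.

    Returns (rs, p, n).
    """
    high = table["high"].to_numpy(dtype=int)
    low = table["low"].to_numpy(dtype=int)
    if (high < 0).any() or (low < 0).any():
        raise ValueError("negative cell counts")
    nonempty = (high + low) > 0
    if nonempty.sum() < 2:
        raise ValueError("need >= 2 nonempty clinical categories")
    x, y = [], []
    for i, (h, lo) in enumerate(zip(high, low)):
        x.extend([i] * (h + lo))
        y.extend([1] * h + [0] * lo)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a margin")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rs) >= 1.0 - 1e-15:
        return rs, 0.0, n
    t = rs * np.sqrt((n - 2) / (1.0 - rs ** 2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rs, p, n


def association_table(long_table: pd.DataFrame) -> pd.DataFrame:
    """Run spearman_ordinal per variable of a long contingency table with
    columns variable, category, high, low (categories listed ascending)."""
    rows = []
    for var, block in long_table.groupby("variable", sort=False):
        rs, p, n = spearman_ordinal(block)
        rows.append({"variable": var, "rs": rs, "p_value": p, "n": n})
    return pd.DataFrame(rows).set_index("variable")


# -------------------------------------------------------------- survival ----
def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step table (time, survival) including t=0 with S=1;
    right-censored subjects (event=0) leave the risk set without an event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no records")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_test(records: pd.DataFrame) -> tuple[float, float]:
    """Two-stratum log-rank test.

    ``records`` columns: time, event, stratum (exactly two levels).
    Returns (chi-square statistic on 1 df, p).
    """
    strata = records["stratum"].unique()
    if len(strata) != 2:
        raise ValueError(f"need exactly two strata, got {list(strata)}")
    a = records[records.stratum == strata[0]]
    b = records[records.stratum == strata[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty stratum")
    if records["event"].sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def km_by_category(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """KM step tables per stratum plus the log-rank comparison."""
    return {s: km_estimate(g["time"], g["event"])
            for s, g in records.groupby("stratum")}


# ----------------------------------------------------------------- ELISA ----
def _four_pl(x, a, b, c, d):
    # a: lower asymptote, d: upper asymptote, c: inflection, b: slope
    return a + (d - a) / (1.0 + (x / c) ** b)


def elisa_readout(standards: pd.DataFrame, sample_od,
                  model: str = "linear_log") -> pd.DataFrame:
    """Inverse-predict concentrations from a fitted standard curve.

    ``standards``: columns concentration, od, with a monotone
    concentration-response relation. model "linear_log" regresses OD on
    log10 concentration; "4pl" fits a four-parameter logistic. Sample ODs
    outside the standards' OD range are flagged unquantifiable (NaN
    concentration).
    """
    conc = standards["concentration"].to_numpy(dtype=float)
    od = standards["od"].to_numpy(dtype=float)
    if conc.size < 3:
        raise ValueError("need >= 3 standards")
    order = np.argsort(conc)
    conc, od = conc[order], od[order]
    diffs = np.diff(od)
    if not ((diffs > 0).all() or (diffs < 0).all()):
        raise ValueError("standards are not monotone in OD")
    sample_od = np.asarray(sample_od, dtype=float)
    lo, hi = od.min(), od.max()
    in_range = (sample_od >= lo) & (sample_od <= hi)

    if model == "linear_log":
        if (conc <= 0).any():
            raise ValueError("linear_log needs positive concentrations")
        slope, intercept = np.polyfit(np.log10(conc), od, 1)
        pred = (sample_od - intercept) / slope
        est = 10.0 ** pred
    elif model == "4pl":
        # y(0) = d, y(inf) = a for b > 0
        p0 = [od[-1], 1.0, float(np.median(conc)), od[0]]
        params, _ = optimize.curve_fit(_four_pl, conc, od, p0=p0,
                                       maxfev=20000)
        a, b, c, d = params

        def invert(y):
            ratio = (d - a) / (y - a) - 1.0
            if ratio <= 0:
                return np.nan
            return c * ratio ** (1.0 / b)

        est = np.array([invert(y) for y in sample_od])
    else:
        raise ValueError(f"unknown model {model!r}")
    est = np.where(in_range, est, np.nan)
    return pd.DataFrame({"od": sample_od, "concentration": est,
                         "quantifiable": in_range})
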