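"""Well-level aggregation, developmental-trajectory tables and the
statistical comparisons used for culture maturation studies.

MEA metrics are aggregated channel → well → timepoint: MFR over active
channels (MFR > 0.1 spikes/s), MBR/BD/RS over channels passing the
bursting filter (MBR ≥ 0.4 bursts/min), NBR at the well level.  Wells with
fewer than 10 of 16 active electrodes at the reference DIV (the timepoint
of maximal mean MFR by default) are excluded from comparisons.  Paired
timepoints are compared with the Wilcoxon signed-rank test and
Benjamini-Hochberg adjustment; two independent groups are compared with
Student's t-test when both pass D'Agostino-Pearson normality, otherwise
with the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import ChannelMetrics, NetworkBurst
from .network import NetworkMetrics, network_metrics

__all__ = [
    "WellSummary",
    "summarize_well",
    "bh_adjust",
    "paired_wilcoxon",
    "compare_two_groups",
    "trajectory_table",
]


@dataclass
class WellSummary:
    """Per-well aggregate of the channel and network metrics."""

    well_id: str
    div: int
    n_channels: int
    n_active: int
    percent_active: float
    mfr: Optional[float]  # mean over active channels, spikes/s
    mbr: Optional[float]  # mean over bursting-included channels, bursts/min
    bd: Optional[float]  # s
    rs: Optional[float]  # %
    nbr: Optional[float]  # network bursts/min
    included: bool = True


def _mean_or_none(values: Sequence[float]) -> Optional[float]:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else None


def summarize_well(
    metrics: Dict[object, ChannelMetrics],
    nbs: Optional[Sequence[NetworkBurst]] = None,
    duration: Optional[float] = None,
    div: int = 0,
    well_id: str = "well",
    n_expected_channels: int = 16,
) -> WellSummary:
    """Aggregate channel metrics into one well row.

    Percent active electrodes uses the expected array size (16 by default)
    as denominator.  MFR averages over active channels; MBR, BD and RS over
    channels passing the bursting-inclusion filter; metrics with no
    qualifying channel are reported missing.  NBR requires ``nbs`` and
    ``duration``.
    """
    mlist = list(metrics.values())
    n_active = sum(m.active for m in mlist)
    active = [m for m in mlist if m.active]
    bursting = [m for m in mlist if m.bursting_included]
    nbr = None
    if nbs is not None and duration is not None:
        nbr = network_metrics(nbs, duration).nbr
    return WellSummary(
        well_id=well_id,
        div=div,
        n_channels=len(mlist),
        n_active=n_active,
        percent_active=100.0 * n_active / n_expected_channels,
        mfr=_mean_or_none([m.mfr for m in active]),
        mbr=_mean_or_none([m.mbr for m in bursting]),
        bd=_mean_or_none([m.bd_mean for m in bursting]),
        rs=_mean_or_none([m.rs for m in bursting]),
        nbr=nbr,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_wilcoxon(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (signed-rank convention); the exact null
    distribution is used for small samples without ties, the normal
    approximation otherwise.  Returns ``(statistic, p, degenerate)``;
    ``degenerate`` is True when fewer than 3 non-zero differences remain,
    in which case the p-value is reported as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size < 3:
        return np.nan, np.nan, True
    stat, p = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           method="auto")
    return float(stat), float(p), False


def compare_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    normality_alpha: float = 0.05,
) -> Dict[str, object]:
    """Two-group comparison with the normality-gated test choice.

    Both groups are checked with the D'Agostino-Pearson normality test;
    when both pass (p > ``normality_alpha``) a two-tailed Student's t-test
    (paired or unpaired) is used, otherwise the Mann-Whitney U test
    (Wilcoxon signed-rank when paired).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # D'Agostino-Pearson requires n >= 8 for a stable k2 statistic
    normal = False
    if a.size >= 8 and b.size >= 8:
        normal = (sps.normaltest(a).pvalue > normality_alpha
                  and sps.normaltest(b).pvalue > normality_alpha)
    if normal:
        test = "paired t-test" if paired else "t-test"
        res = sps.ttest_rel(a, b) if paired else sps.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    elif paired:
        test = "wilcoxon"
        stat, p, _ = paired_wilcoxon(a, b)
    else:
        test = "mann-whitney"
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return {"test": test, "statistic": stat, "p": p, "normal": normal,
            "n": (int(a.size), int(b.size))}


def _apply_well_filter(
    df: pd.DataFrame, reference_div: Optional[int], min_active: int
) -> Tuple[pd.DataFrame, int]:
    """Drop wells with < ``min_active`` active electrodes at the reference
    DIV (the DIV of maximal mean MFR when not given)."""
    if reference_div is None:
        by_div = df.groupby("div")["mfr"].mean()
        reference_div = int(by_div.idxmax())
    ref = df[df["div"] == reference_div]
    bad_wells = set(ref.loc[ref["n_active"] < min_active, "well_id"])
    return df[~df["well_id"].isin(bad_wells)].reset_index(drop=True), reference_div


def trajectory_table(
    summaries: Sequence[WellSummary],
    metrics: Sequence[str] = ("mfr", "mbr", "bd", "rs", "nbr", "percent_active"),
    reference_div: Optional[int] = None,
    min_active_electrodes: int = 10,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Developmental-trajectory table plus consecutive-DIV comparisons.

    Returns ``(table, comparisons)``: per-DIV mean ± SD of each metric over
    included wells (n = wells), and Wilcoxon signed-rank comparisons of
    each metric between consecutive DIVs over wells present at both, with
    Benjamini-Hochberg adjustment across all comparisons.  The well filter
    (≥ ``min_active_electrodes`` of 16 active at the reference DIV) is
    applied before both outputs.
    """
    df = pd.DataFrame([vars(s) for s in summaries])
    if df.empty or df["div"].nunique() < 1:
        raise ValueError("need well summaries from at least one DIV")
    df, ref_div = _apply_well_filter(df, reference_div, min_active_electrodes)

    rows = []
    for div, g in df.groupby("div"):
        for m in metrics:
            vals = g[m].dropna()
            rows.append({
                "div": div, "metric": m, "n": int(vals.size),
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "sem": float(vals.sem()) if vals.size > 1 else np.nan,
            })
    table = pd.DataFrame(rows)

    comps = []
    divs = sorted(df["div"].unique())
    for d1, d2 in zip(divs[:-1], divs[1:]):
        a = df[df["div"] == d1].set_index("well_id")
        b = df[df["div"] == d2].set_index("well_id")
        common = a.index.intersection(b.index)
        for m in metrics:
            pair = pd.concat([a.loc[common, m], b.loc[common, m]], axis=1).dropna()
            if len(pair) < 3:
                continue
            stat, p, degenerate = paired_wilcoxon(
                pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            )
            comps.append({"metric": m, "div_a": d1, "div_b": d2,
                          "statistic": stat, "p_raw": p, "n": len(pair),
                          "degenerate": degenerate})
    comparisons = pd.DataFrame(comps)
    if not comparisons.empty:
        ok = ~comparisons["p_raw"].isna()
        adj = np.full(len(comparisons), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = bh_adjust(comparisons.loc[ok, "p_raw"].to_numpy())
        comparisons["p_adj"] = adj
    table.attrs["reference_div"] = ref_div
    return table, comparisons
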