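"""Developmental-trajectory statistics: well summaries across culture
ages (DIV), the 10-of-16 active-electrode well filter, and paired
Wilcoxon comparisons with Benjamini-Hochberg adjustment.

Run:  python examples/timepoint_statistics.py
"""

import numpy as np

from neurodish.stats_report import WellSummary, trajectory_table

rng = np.random.default_rng(2)
divs = (7, 14, 21, 28, 35, 42, 49)
mfr_means = (0.05, 0.2, 0.6, 1.2, 2.0, 2.8, 3.2)  # maturing firing rate

summaries = []
for div, mu in zip(divs, mfr_means):
    for w in range(8):
        n_active = min(16, rng.binomial(16, min(0.3 + div / 60, 1.0)))
        summaries.append(WellSummary(
            well_id=f"w{w}", div=div, n_channels=16, n_active=n_active,
            percent_active=100 * n_active / 16,
            mfr=max(mu + rng.normal(0, 0.1 * mu + 0.01), 0.0),
            mbr=None, bd=None, rs=None, nbr=None))

table, comparisons = trajectory_table(summaries, metrics=("mfr",))
print(f"reference DIV (max mean MFR): {table.attrs['reference_div']}")
print(table.pivot(index="div", columns="metric", values="mean").round(3))
print("\nconsecutive-DIV paired Wilcoxon (BH adjusted):")
print(comparisons[["div_a", "div_b", "n", "p_raw", "p_adj"]].round(4).to_string(index=False))
print("\nAdjusted p-values < 0.05 mark timepoint-to-timepoint increases in "
      "firing that exceed chance, after correcting across all comparisons.")
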