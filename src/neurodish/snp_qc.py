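"""SNP-array probe preprocessing for allele-specific copy-number analysis.

Produces the segmentation-ready table of logR / BAF values from a raw
GenomeStudio-style probe export: sequential exclusion filters, duplicate
aggregation, and the logR transform logR = γ·log2(R) with γ = 0.55.
Segmentation itself (ASCAT-family tools) is downstream of this module.
"""

from __future__ import annotations

import logging
from typing import Dict, Tuple

import numpy as np
import pandas as pd

__all__ = ["filter_probes", "aggregate_duplicates", "compute_logR", "preprocess"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("probe_id", "chromosome", "position", "snp_type", "R", "BAF")

#: chromosome labels excluded from autosomal copy-number analysis
EXCLUDED_CHROMOSOMES = frozenset({"X", "Y", "XY", "0", "MT"})
#: probe types excluded
EXCLUDED_SNP_TYPES = frozenset({"INDEL", "DELETION"})


def _check_columns(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"probe table is missing required columns: {missing}")


def filter_probes(table: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply the exclusion filters sequentially and count removals per filter.

    Order: (1) sex chromosomes (X, Y, XY) plus chromosomes 0 and MT;
    (2) position 0; (3) missing R or BAF; (4) SNP type Indel or Deletion.
    A probe failing several filters is counted once, at the first filter
    that removes it.  Chromosome and type labels are matched
    case-insensitively.
    """
    _check_columns(table)
    counts: Dict[str, int] = {}
    df = table

    chrom = df["chromosome"].astype(str).str.upper().str.strip()
    drop = chrom.isin(EXCLUDED_CHROMOSOMES)
    counts["chromosome"] = int(drop.sum())
    df = df[~drop]

    drop = df["position"].fillna(0).astype(np.int64) == 0
    counts["position"] = int(drop.sum())
    df = df[~drop]

    drop = df["R"].isna() | df["BAF"].isna()
    counts["missing"] = int(drop.sum())
    df = df[~drop]

    snp_type = df["snp_type"].astype(str).str.upper().str.strip()
    drop = snp_type.isin(EXCLUDED_SNP_TYPES)
    counts["snp_type"] = int(drop.sum())
    df = df[~drop]

    return df.reset_index(drop=True), counts


def aggregate_duplicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated probe ids to one row each.

    Groups of exactly two duplicates take the mean of R and BAF; groups of
    more than two take the median; singletons pass through unchanged.
    Non-intensity columns take the first value of the group.  Idempotent.
    """
    _check_columns(table)
    if table["probe_id"].is_unique:
        return table.reset_index(drop=True)

    def _agg(g: pd.DataFrame) -> pd.Series:
        out = g.iloc[0].copy()
        if len(g) == 2:
            out["R"] = g["R"].mean()
            out["BAF"] = g["BAF"].mean()
        elif len(g) > 2:
            out["R"] = g["R"].median()
            out["BAF"] = g["BAF"].median()
        return out

    out = (
        table.groupby("probe_id", sort=False, group_keys=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return out[list(table.columns)]


def compute_logR(table: pd.DataFrame, gamma: float = 0.55) -> pd.DataFrame:
    """Add the logR column: logR = γ·log2(R), γ = 0.55 by default.

    Probes with R ≤ 0 cannot be log-transformed and are dropped with a
    logged count.
    """
    if "R" not in table.columns:
        raise ValueError("probe table has no column 'R'")
    bad = table["R"] <= 0
    if bad.any():
        logger.warning("dropping %d probes with non-positive R", int(bad.sum()))
        table = table[~bad]
    out = table.copy()
    out["logR"] = gamma * np.log2(out["R"].to_numpy(dtype=float))
    return out.reset_index(drop=True)


def preprocess(
    table: pd.DataFrame, gamma: float = 0.55
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Full chain: filter → aggregate duplicates → logR."""
    filtered, counts = filter_probes(table)
    deduped = aggregate_duplicates(filtered)
    counts["duplicates_collapsed"] = len(filtered) - len(deduped)
    return compute_logR(deduped, gamma=gamma), counts
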