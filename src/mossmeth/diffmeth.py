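"""Comparative methylation statistics between two samples.

The central statistic is the signed percent methylation change: the
difference between two fractional methylation levels divided by the larger
of the two, as a percentage. Positive values mean higher methylation in
sample B (the mutant, by pipeline convention), negative values lower.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .calling import CONTEXTS, assign_windows_to_tes
from .genome import GenomeBundle

logger = logging.getLogger(__name__)


def percent_change(m_a, m_b):
    """Signed percent methylation change from sample A to sample B.

    ``100 * (m_b - m_a) / max(m_a, m_b)``; defined as 0 when both levels
    are 0 (no evidence of change). Accepts scalars or arrays; inputs must
    lie in [0, 1]. The magnitude is 100 exactly when one level is 0 and
    the other positive.
    """
    a = np.asarray(m_a, dtype=float)
    b = np.asarray(m_b, dtype=float)
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise ValueError("methylation fractions must be in [0, 1]")
    hi = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        # divide before scaling: the ratio is exactly +/-1 when one level is 0,
        # so the boundary value is exactly +/-100
        out = np.where(hi > 0, (b - a) / np.where(hi > 0, hi, 1.0) * 100.0, 0.0)
    if np.isscalar(m_a) and np.isscalar(m_b):
        return float(out)
    return out


def percent_change_table(
    windows_a: pd.DataFrame,
    windows_b: pd.DataFrame,
    context: str = "CG",
    te_only: bool = False,
    genome: GenomeBundle | None = None,
) -> pd.DataFrame:
    """Window-level percent change for one context.

    Only windows whose fraction is defined in both samples enter the table
    (the coordinate grids must match). With ``te_only`` windows are
    restricted to those assigned to a TE (>= 50% overlap).
    """
    col = f"m{context}" if context in CONTEXTS else "m_total"
    key = ["chrom", "start", "end"]
    merged = windows_a[key + [col]].merge(
        windows_b[key + [col]], on=key, suffixes=("_a", "_b")
    )
    merged = merged.dropna(subset=[f"{col}_a", f"{col}_b"]).reset_index(drop=True)
    if te_only:
        if genome is None:
            raise ValueError("te_only requires the genome bundle")
        te_ids = assign_windows_to_tes(merged, genome)
        merged = merged[te_ids >= 0].reset_index(drop=True)
    out = merged.rename(columns={f"{col}_a": "m_a", f"{col}_b": "m_b"})
    out["context"] = context
    out["pct_change"] = percent_change(out["m_a"].values, out["m_b"].values)
    return out


def select_matched_windows(
    windows_a: pd.DataFrame, windows_b: pd.DataFrame, min_meth: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windows with equal CG and CHG covered-site counts and high methylation.

    Keeps windows where both samples define mCG and mCHG, the covered CG
    and CHG site counts agree (and are >= 1) in both samples, and the
    maximum of the four symmetric-context levels exceeds ``min_meth``.
    Returns ``(matched, summary)`` where summary holds the median and
    quartiles of the per-sample mCG - mCHG difference.
    """
    key = ["chrom", "start", "end"]
    cols = ["mCG", "mCHG", "sites_CG", "sites_CHG"]
    merged = windows_a[key + cols].merge(windows_b[key + cols], on=key, suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["mCG_a", "mCHG_a", "mCG_b", "mCHG_b"])
    eq = (
        (merged["sites_CG_a"] == merged["sites_CHG_a"])
        & (merged["sites_CG_b"] == merged["sites_CHG_b"])
        & (merged["sites_CG_a"] >= 1)
        & (merged["sites_CG_b"] >= 1)
    )
    peak = merged[["mCG_a", "mCHG_a", "mCG_b", "mCHG_b"]].max(axis=1)
    matched = merged[eq & (peak > min_meth)].reset_index(drop=True)
    if matched.empty:
        logger.warning("no matched CG/CHG windows passed min_meth=%s", min_meth)
    matched["diff_a"] = matched["mCG_a"] - matched["mCHG_a"]
    matched["diff_b"] = matched["mCG_b"] - matched["mCHG_b"]
    summary = pd.DataFrame(
        {
            "sample": ["a", "b"],
            "n_windows": [len(matched)] * 2,
            "median": [matched["diff_a"].median(), matched["diff_b"].median()],
            "q1": [matched["diff_a"].quantile(0.25), matched["diff_b"].quantile(0.25)],
            "q3": [matched["diff_a"].quantile(0.75), matched["diff_b"].quantile(0.75)],
        }
    )
    return matched, summary


def stratify_by_attribute(
    change_records: pd.DataFrame, attribute: np.ndarray | pd.Series, n_quantiles: int = 5
) -> pd.DataFrame:
    """Summarise percent change within equal-size quantile groups.

    Windows are ranked by the attribute (ties broken by input/coordinate
    order, so a constant attribute yields coordinate-ordered groups) and
    split into ``n_quantiles`` near-equal groups from lowest to highest.
    """
    attr = np.asarray(attribute, dtype=float)
    if len(attr) != len(change_records):
        raise ValueError("attribute must align with change records")
    if len(change_records) < n_quantiles:
        raise ValueError("fewer windows than quantiles")
    order = np.argsort(attr, kind="stable")
    groups = np.array_split(order, n_quantiles)
    rows = []
    pct = change_records["pct_change"].values
    for qi, g in enumerate(groups):
        vals = pct[g]
        rows.append(
            {
                "quantile": qi + 1,
                "n": len(g),
                "attr_min": float(attr[g].min()),
                "attr_max": float(attr[g].max()),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
                "mean": float(np.mean(vals)),
            }
        )
    return pd.DataFrame(rows)


def chromosome_profile(
    records: pd.DataFrame,
    genome: GenomeBundle,
    window: int = 100_000,
    step: int | None = None,
) -> pd.DataFrame:
    """Weighted per-context methylation in large chromosome-scale bins.

    ``step=None`` gives non-overlapping tiles of ``window`` bp. Empty bins
    appear with NaN (a gap in the exported track).
    """
    step = window if step is None else step
    frames = []
    for chrom in genome.chroms:
        L = genome.chrom_length(chrom)
        starts = np.arange(0, L, step, dtype=np.int64)
        rec = records[records["chrom"] == chrom]
        pos = rec["pos"].values
        row = {"chrom": chrom, "start": starts, "end": np.minimum(starts + window, L)}
        for ctx in CONTEXTS:
            sel = (rec["context"] == ctx).values
            nc = np.zeros(len(starts))
            nt = np.zeros(len(starts))
            for s_i, s in enumerate(starts):
                inwin = sel & (pos >= s) & (pos < s + window)
                nc[s_i] = rec["n_C"].values[inwin].sum()
                nt[s_i] = rec["n_T"].values[inwin].sum()
            with np.errstate(invalid="ignore"):
                row[f"m{ctx}"] = np.where(nc + nt > 0, nc / np.maximum(nc + nt, 1), np.nan)
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)


def estimate_context_reduction(
    windows_wt: pd.DataFrame,
    windows_mut: pd.DataFrame,
    genome: GenomeBundle,
) -> pd.DataFrame:
    """TE-wide per-context methylation and its percent reduction.

    Aggregates counts over all TE-assigned windows per sample, then applies
    the percent-change statistic to the aggregate levels. ``pct_reduction``
    is positive when the mutant is lower — the pipeline's headline summary.
    """
    te_wt = windows_wt[assign_windows_to_tes(windows_wt, genome) >= 0]
    te_mut = windows_mut[assign_windows_to_tes(windows_mut, genome) >= 0]
    rows = []
    for ctx in CONTEXTS:
        nc_wt = float(te_wt[f"nC_{ctx}"].sum())
        nt_wt = float(te_wt[f"nT_{ctx}"].sum())
        nc_mut = float(te_mut[f"nC_{ctx}"].sum())
        nt_mut = float(te_mut[f"nT_{ctx}"].sum())
        if nc_wt + nt_wt == 0 or nc_mut + nt_mut == 0:
            raise ValueError(f"no covered {ctx} sites in TEs for one of the samples")
        m_wt = nc_wt / (nc_wt + nt_wt)
        m_mut = nc_mut / (nc_mut + nt_mut)
        pc = percent_change(m_wt, m_mut)
        rows.append(
            {
                "context": ctx,
                "m_wt": m_wt,
                "m_mut": m_mut,
                "pct_change": pc,
                "pct_reduction": -pc,
            }
        )
    return pd.DataFrame(rows)
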