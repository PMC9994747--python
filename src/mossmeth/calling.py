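"""Cytosine context assignment and windowed fractional methylation.

Methylation of a cytosine is read out from bisulfite evidence as
``n_C / (n_C + n_T)``; regional (weighted) methylation always pools counts
before dividing, i.e. ``sum(n_C) / sum(n_C + n_T)``, never averages of
per-site ratios.

Contexts follow the plant convention: CG, CHG and CHH, with H = A, C or T,
read strandwise (for a minus-strand cytosine the downstream bases lie at
decreasing plus-strand coordinates and are complemented).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _sequtils as sq
from .genome import GenomeBundle

CONTEXTS = ("CG", "CHG", "CHH")
CTX_CG, CTX_CHG, CTX_CHH, CTX_NONE = 0, 1, 2, -1
CONTEXT_NAMES = {CTX_CG: "CG", CTX_CHG: "CHG", CTX_CHH: "CHH"}


def context_arrays(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position context codes for both strands of one chromosome.

    Returns ``(ctx_plus, ctx_minus)`` int8 arrays where plus entries are
    defined at plus-strand C positions and minus entries at plus-strand G
    positions (a C on the minus strand). A cytosine whose two strandwise
    downstream bases are not both defined (N or off-chromosome) gets -1.
    """
    L = len(seq)
    ctx_plus = np.full(L, CTX_NONE, dtype=np.int8)
    ctx_minus = np.full(L, CTX_NONE, dtype=np.int8)
    if L < 3:
        return ctx_plus, ctx_minus

    is_c = seq == sq.C
    is_g = seq == sq.G

    # plus strand: downstream bases at +1, +2
    b1 = seq[1:-1]
    b2 = seq[2:]
    ok = is_c[:-2] & (b1 != sq.N) & (b2 != sq.N)
    lab = np.where(b1 == sq.G, CTX_CG, np.where(b2 == sq.G, CTX_CHG, CTX_CHH))
    ctx_plus[:-2][ok] = lab[ok].astype(np.int8)

    # minus strand: strandwise downstream bases sit at -1, -2 on the plus
    # strand; "G" on the minus strand is a plus-strand C.
    b1m = seq[1:-1]
    b2m = seq[:-2]
    okm = is_g[2:] & (b1m != sq.N) & (b2m != sq.N)
    labm = np.where(b1m == sq.C, CTX_CG, np.where(b2m == sq.C, CTX_CHG, CTX_CHH))
    ctx_minus[2:][okm] = labm[okm].astype(np.int8)

    return ctx_plus, ctx_minus


def assign_context(genome: GenomeBundle, chrom: str, pos: int, strand: str) -> str | None:
    """Context label of one genomic cytosine, or None near edges/N bases."""
    seq = genome.seqs[chrom]
    base = seq[pos]
    if strand == "+":
        if base != sq.C:
            raise ValueError(f"{chrom}:{pos}(+) is not a cytosine")
        code = context_arrays(seq)[0][pos]
    elif strand == "-":
        if base != sq.G:
            raise ValueError(f"{chrom}:{pos}(-) is not a cytosine")
        code = context_arrays(seq)[1][pos]
    else:
        raise ValueError(f"invalid strand {strand!r}")
    return CONTEXT_NAMES.get(int(code))


def trinucleotide(genome: GenomeBundle, chrom: str, pos: int, strand: str) -> str:
    """Strandwise trinucleotide starting at the cytosine (padded with N)."""
    seq = genome.seqs[chrom]
    if strand == "+":
        tri = seq[pos : pos + 3]
        out = sq.decode(tri)
        return out + "N" * (3 - len(out))
    tri = seq[max(0, pos - 2) : pos + 1]
    out = sq.decode(sq.revcomp(tri))
    return out + "N" * (3 - len(out))


def window_methylation(
    records: pd.DataFrame,
    genome: GenomeBundle,
    width: int = 50,
    step: int | None = None,
    min_calls: int = 4,
) -> pd.DataFrame:
    """Tile chromosomes into windows and compute fractional methylation.

    Parameters
    ----------
    records:
        Per-cytosine table with columns chrom, pos, strand, context,
        n_C, n_T (both strands pooled into the same windows).
    width, step:
        Window width and start spacing in bp; ``step=None`` means
        non-overlapping tiles (step = width).
    min_calls:
        Minimum informative calls (n_C + n_T) for a context fraction to be
        defined; below it the fraction is NaN.

    Returns
    -------
    One row per window with per-context counts (``nC_CG`` ...), covered-site
    counts (``sites_CG`` ...), per-context fractions (``mCG`` ...), the
    pooled ``m_total``, and ``coverage`` (mean calls per covered site).
    """
    if width < 1 or (step is not None and step < 1):
        raise ValueError("width and step must be >= 1")
    step = width if step is None else step

    rec = records[(records["n_C"] + records["n_T"]) > 0]
    n_phases = -(-width // step)  # ceil: windows covering one position
    pieces = []
    for j in range(n_phases):
        widx = rec["pos"].values // step - j
        start = widx * step
        ok = (start >= 0) & (rec["pos"].values < start + width)
        sub = pd.DataFrame(
            {
                "chrom": rec["chrom"].values[ok],
                "start": start[ok],
                "context": rec["context"].values[ok],
                "n_C": rec["n_C"].values[ok],
                "n_T": rec["n_T"].values[ok],
            }
        )
        pieces.append(sub)
    empty = pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "context": pd.Series(dtype=str),
            "n_C": pd.Series(dtype=np.int64),
            "n_T": pd.Series(dtype=np.int64),
        }
    )
    allrec = pd.concat(pieces, ignore_index=True) if pieces else empty

    grouped = (
        allrec.groupby(["chrom", "start", "context"], observed=True)
        .agg(n_C=("n_C", "sum"), n_T=("n_T", "sum"), sites=("n_C", "size"))
        .reset_index()
        .astype({"n_C": np.int64, "n_T": np.int64, "sites": np.int64})
    )

    # full tiling so empty windows appear (flagged undefined)
    frames = []
    for chrom in genome.chroms:
        starts = np.arange(0, genome.chrom_length(chrom), step, dtype=np.int64)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts}))
    windows = pd.concat(frames, ignore_index=True)
    windows["end"] = np.minimum(
        windows["start"] + width,
        windows["chrom"].map({c: genome.chrom_length(c) for c in genome.chroms}),
    )

    for ctx in CONTEXTS:
        sub = grouped[grouped["context"] == ctx].set_index(["chrom", "start"])
        key = pd.MultiIndex.from_frame(windows[["chrom", "start"]])
        windows[f"nC_{ctx}"] = sub["n_C"].reindex(key).fillna(0).astype(np.int64).values
        windows[f"nT_{ctx}"] = sub["n_T"].reindex(key).fillna(0).astype(np.int64).values
        windows[f"sites_{ctx}"] = (
            sub["sites"].reindex(key).fillna(0).astype(np.int64).values
        )
        calls = windows[f"nC_{ctx}"] + windows[f"nT_{ctx}"]
        frac = np.where(calls >= min_calls, windows[f"nC_{ctx}"] / calls.where(calls > 0), np.nan)
        windows[f"m{ctx}"] = frac

    nc_tot = sum(windows[f"nC_{c}"] for c in CONTEXTS)
    calls_tot = nc_tot + sum(windows[f"nT_{c}"] for c in CONTEXTS)
    windows["m_total"] = np.where(
        calls_tot >= min_calls, nc_tot / calls_tot.where(calls_tot > 0), np.nan
    )
    sites_tot = sum(windows[f"sites_{c}"] for c in CONTEXTS)
    windows["coverage"] = np.where(sites_tot > 0, calls_tot / sites_tot.where(sites_tot > 0), np.nan)
    return windows


def weighted_fraction(records: pd.DataFrame, context: str | None = None) -> float:
    """Pooled n_C / (n_C + n_T) over a record set; NaN when uncovered."""
    sub = records if context is None else records[records["context"] == context]
    denom = float(sub["n_C"].sum() + sub["n_T"].sum())
    return float(sub["n_C"].sum()) / denom if denom > 0 else float("nan")


def region_methylation(
    records: pd.DataFrame,
    regions: pd.DataFrame,
    genome: GenomeBundle,
    context: str | None = None,
    part: str = "whole",
) -> pd.DataFrame:
    """Weighted methylation per annotated region.

    ``part`` selects the sub-interval for LTR-class TEs: ``whole`` (any
    region), ``internal`` (element minus its two terminal LTRs) or ``ltr``
    (the two LTR copies pooled). Regions without LTR annotation are skipped
    for the sub-parts and reported with NaN.
    """
    if part not in ("whole", "internal", "ltr"):
        raise ValueError(f"unknown part {part!r}")

    label = {c: np.full(genome.chrom_length(c), -1, dtype=np.int32) for c in genome.chroms}
    skipped = 0
    for idx, row in regions.iterrows():
        chrom = row["chrom"]
        if part == "whole":
            label[chrom][int(row["start"]) : int(row["end"])] = idx
            continue
        has_ltr = pd.notna(row.get("ltr5_start"))
        if not has_ltr:
            skipped += 1
            continue
        if part == "ltr":
            label[chrom][int(row["ltr5_start"]) : int(row["ltr5_end"])] = idx
            label[chrom][int(row["ltr3_start"]) : int(row["ltr3_end"])] = idx
        else:  # internal
            label[chrom][int(row["ltr5_end"]) : int(row["ltr3_start"])] = idx

    rec = records if context is None else records[records["context"] == context]
    ids = np.empty(len(rec), dtype=np.int32)
    for chrom, sub_idx in rec.groupby("chrom", observed=True).indices.items():
        ids[sub_idx] = label[chrom][rec["pos"].values[sub_idx]]
    rec = rec.assign(_region=ids)
    rec = rec[rec["_region"] >= 0]
    sums = rec.groupby("_region")[["n_C", "n_T"]].sum()

    out = pd.DataFrame(index=regions.index)
    out["n_C"] = sums["n_C"].reindex(regions.index).fillna(0).astype(np.int64)
    out["n_T"] = sums["n_T"].reindex(regions.index).fillna(0).astype(np.int64)
    calls = out["n_C"] + out["n_T"]
    out["fraction"] = np.where(calls > 0, out["n_C"] / calls.where(calls > 0), np.nan)
    if part != "whole":
        no_ltr = regions["ltr5_start"].isna() if "ltr5_start" in regions else pd.Series(True, index=regions.index)
        out.loc[no_ltr, ["n_C", "n_T"]] = 0
        out.loc[no_ltr, "fraction"] = np.nan
    out.attrs["skipped_no_ltr"] = skipped
    return out


def te_methylation_table(
    records_by_sample: dict[str, pd.DataFrame],
    genome: GenomeBundle,
    context: str | None = None,
) -> pd.DataFrame:
    """Per-TE whole/internal/LTR weighted methylation for each sample."""
    out = genome.tes[["chrom", "start", "end", "strand", "name", "family", "te_class"]].copy()
    for sample, rec in records_by_sample.items():
        for part in ("whole", "internal", "ltr"):
            frac = region_methylation(rec, genome.tes, genome, context=context, part=part)
            out[f"m_{part}_{sample}"] = frac["fraction"]
    return out


def assign_windows_to_tes(
    windows: pd.DataFrame, genome: GenomeBundle, min_overlap: float = 0.5
) -> np.ndarray:
    """TE row index per window (-1 if < ``min_overlap`` of the window is TE)."""
    te_ids = genome.te_id_arrays
    cums = {c: np.concatenate([[0], np.cumsum(te_ids[c] >= 0)]) for c in genome.chroms}
    out = np.full(len(windows), -1, dtype=np.int64)
    for i, (chrom, start, end) in enumerate(
        zip(windows["chrom"].values, windows["start"].values, windows["end"].values)
    ):
        width = end - start
        if width <= 0:
            continue
        ov = cums[chrom][end] - cums[chrom][start]
        if ov >= min_overlap * width:
            ids = te_ids[chrom][start:end]
            ids = ids[ids >= 0]
            vals, counts = np.unique(ids, return_counts=True)
            out[i] = vals[np.argmax(counts)]
    return out
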