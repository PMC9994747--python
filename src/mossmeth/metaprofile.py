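"""Methylation meta-profiles around TE boundaries.

TEs are aligned at their 5' or 3' end (strandwise) and methylation is
averaged in fixed-width bins of strandwise offset from that anchor.
Positive offsets run into the element, negative offsets into flanking
sequence. Each element contributes until it reaches its own far boundary,
the first base of another annotated feature (any gene or TE), or the
requested maximum offset — whichever comes first. Per-offset values are
count-weighted means pooled over contributing elements, so they equal a
regional weighted methylation over the same truncated footprints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import CONTEXTS
from .genome import GenomeBundle


def _context_cumsums(records: pd.DataFrame, genome: GenomeBundle):
    """Cumulative per-position n_C / n_T per context (strands pooled)."""
    nc = {c: {ch: np.zeros(genome.chrom_length(ch)) for ch in genome.chroms} for c in CONTEXTS}
    nt = {c: {ch: np.zeros(genome.chrom_length(ch)) for ch in genome.chroms} for c in CONTEXTS}
    for (chrom, ctx), sub in records.groupby(["chrom", "context"], observed=True):
        np.add.at(nc[ctx][chrom], sub["pos"].values, sub["n_C"].values)
        np.add.at(nt[ctx][chrom], sub["pos"].values, sub["n_T"].values)
    cum = lambda a: np.concatenate([[0.0], np.cumsum(a)])
    return (
        {c: {ch: cum(v) for ch, v in d.items()} for c, d in nc.items()},
        {c: {ch: cum(v) for ch, v in d.items()} for c, d in nt.items()},
    )


def te_metaprofile(
    records_by_sample: dict[str, pd.DataFrame],
    genome: GenomeBundle,
    anchor: str = "5prime",
    bin: int = 100,
    max_offset: int = 2000,
) -> pd.DataFrame:
    """Meta-profile of methylation around TE ends.

    Parameters
    ----------
    records_by_sample:
        ``{sample: cytosine record table}``; all samples are profiled over
        the identical element set and footprints.
    anchor:
        ``5prime`` or ``3prime`` — which strandwise element end to align.
    bin, max_offset:
        Bin width and maximum |offset| in bp.

    Returns a long-format table (anchor, offset, context, sample, value,
    n_C, n_T, n_elements); ``offset`` is the bin's strandwise start, so bin
    [0, bin) covers the first bases inside the element and bin [-bin, 0)
    the bases immediately outside the anchor.
    """
    if anchor not in ("5prime", "3prime"):
        raise ValueError(f"anchor must be 5prime or 3prime, got {anchor!r}")
    if genome.tes.empty:
        raise ValueError("empty TE set")
    if bin < 1 or max_offset < bin:
        raise ValueError("need bin >= 1 and max_offset >= bin")

    per_sample = {s: _context_cumsums(rec, genome) for s, rec in records_by_sample.items()}
    annotated = genome.annotated_arrays
    n_bins = max_offset // bin
    offsets = np.concatenate([-np.arange(1, n_bins + 1)[::-1] * bin, np.arange(n_bins) * bin])

    acc_nc = {(s, c): np.zeros(2 * n_bins) for s in records_by_sample for c in CONTEXTS}
    acc_nt = {(s, c): np.zeros(2 * n_bins) for s in records_by_sample for c in CONTEXTS}
    n_elements = np.zeros(2 * n_bins, dtype=np.int64)

    for _, row in genome.tes.iterrows():
        chrom = row["chrom"]
        L = genome.chrom_length(chrom)
        start, end, strand = int(row["start"]), int(row["end"]), row["strand"]
        # anchor base and the genomic direction of increasing offset
        if (anchor == "5prime") == (strand == "+"):
            apos, inward = start, +1
        else:
            apos, inward = end - 1, -1

        t_in = min(end - start, max_offset)  # inside reach: own boundary
        if inward == +1:
            flank = annotated[chrom][max(0, apos - max_offset) : apos][::-1]
        else:
            flank = annotated[chrom][apos + 1 : min(L, apos + 1 + max_offset)]
        hitpos = np.flatnonzero(flank)
        t_out = int(hitpos[0]) if len(hitpos) else len(flank)  # outside reach

        ranges = []  # (bin index, genomic lo, genomic hi)
        for b in range(n_bins):  # inside bins, offset b*bin
            ln = int(np.clip(t_in - b * bin, 0, bin))
            if ln == 0:
                continue
            if inward == +1:
                lo = apos + b * bin
                ranges.append((n_bins + b, lo, lo + ln))
            else:
                hi = apos - b * bin + 1
                ranges.append((n_bins + b, hi - ln, hi))
        for j in range(1, n_bins + 1):  # outside bins, offset -j*bin
            ln = int(np.clip(t_out - (j - 1) * bin, 0, bin))
            if ln == 0:
                continue
            if inward == +1:
                hi = apos - (j - 1) * bin
                ranges.append((n_bins - j, hi - ln, hi))
            else:
                lo = apos + (j - 1) * bin + 1
                ranges.append((n_bins - j, lo, lo + ln))

        for b, lo, hi in ranges:
            n_elements[b] += 1
            for s, (cnc, cnt) in per_sample.items():
                for ctx in CONTEXTS:
                    acc_nc[(s, ctx)][b] += cnc[ctx][chrom][hi] - cnc[ctx][chrom][lo]
                    acc_nt[(s, ctx)][b] += cnt[ctx][chrom][hi] - cnt[ctx][chrom][lo]

    rows = []
    for (s, ctx) in acc_nc:
        tot = acc_nc[(s, ctx)] + acc_nt[(s, ctx)]
        with np.errstate(invalid="ignore"):
            val = np.where(tot > 0, acc_nc[(s, ctx)] / np.maximum(tot, 1), np.nan)
        for b in range(2 * n_bins):
            rows.append(
                {
                    "anchor": anchor,
                    "offset": int(offsets[b]),
                    "context": ctx,
                    "sample": s,
                    "value": val[b],
                    "n_C": acc_nc[(s, ctx)][b],
                    "n_T": acc_nt[(s, ctx)][b],
                    "n_elements": int(n_elements[b]),
                }
            )
    return pd.DataFrame(rows).sort_values(["sample", "context", "offset"], ignore_index=True)
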