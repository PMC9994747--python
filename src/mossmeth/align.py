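"""Three-letter bisulfite read alignment and per-cytosine pileup.

Alignment is methylation-insensitive: reads and reference are collapsed to
a three-letter alphabet (C->T for the plus bisulfite template, G->A for the
minus template) and matched ungapped end-to-end. For each read both
template-strand hypotheses are searched; hits with the minimum mismatch
count (at most ``max_mismatches``) are pooled across hypotheses, reads with
more than ``max_hits`` equally good placements are discarded, and among the
survivors one placement is chosen by a seeded uniform draw with the tie
multiplicity recorded.

The search is seed-and-extend with a pigeonhole guarantee: a read allowed
``m`` mismatches is split into ``m + 1`` segments, at least one of which is
exact, so looking up each segment's leading k-mer in the converted-genome
index finds every valid placement. Reads too short for that many disjoint
k-mers fall back to an exhaustive scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _sequtils as sq
from .calling import CONTEXT_NAMES, context_arrays, trinucleotide
from .genome import GenomeBundle

logger = logging.getLogger(__name__)

DEFAULT_SEED_K = 20


@dataclass
class ConvertedIndex:
    """Converted reference sequences plus exact k-mer position indexes."""

    genome: GenomeBundle
    k: int = DEFAULT_SEED_K
    converted: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)  # mode -> chrom -> seq
    seeds: dict[str, dict[bytes, np.ndarray]] = field(default_factory=dict)  # mode -> kmer -> rows
    _positions: dict[str, dict[bytes, list]] = field(default_factory=dict, repr=False)


def build_converted_index(genome: GenomeBundle, k: int = DEFAULT_SEED_K) -> ConvertedIndex:
    """Convert the reference under both bisulfite modes and index k-mers.

    Mode ``CT`` holds the C->T-converted plus strand (no C outside N runs),
    mode ``GA`` the G->A-converted plus strand (no G). N bases are kept.
    Chromosomes shorter than ``k`` are stored unseeded with a warning.
    """
    if not genome.seqs:
        raise ValueError("empty genome")
    idx = ConvertedIndex(genome=genome, k=k)
    for mode, conv in (("CT", sq.convert_ct), ("GA", sq.convert_ga)):
        idx.converted[mode] = {c: conv(s) for c, s in genome.seqs.items()}
        table: dict[bytes, list] = {}
        for ci, (chrom, arr) in enumerate(idx.converted[mode].items()):
            if len(arr) < k:
                logger.warning("chromosome %s shorter than k=%d; not seeded", chrom, k)
                continue
            b = arr.tobytes()
            for p in range(len(b) - k + 1):
                table.setdefault(b[p : p + k], []).append((ci, p))
        idx.seeds[mode] = {
            kmer: np.asarray(locs, dtype=np.int64) for kmer, locs in table.items()
        }
    return idx


@dataclass
class AlignmentHit:
    """One chosen placement of a read on the original genome."""

    read_id: str
    chrom: str
    start: int  # 0-based, plus-strand coordinates
    strand: str  # template strand of origin: '+' or '-'
    mismatches: int
    multiplicity: int
    oriented_seq: np.ndarray | None = None  # original read, plus-strand orientation
    exclude: tuple[int, int] | None = None  # interval masked out in pileup (mate overlap)

    @property
    def end(self) -> int:
        return self.start + (len(self.oriented_seq) if self.oriented_seq is not None else 0)


def _candidate_hits(query: np.ndarray, index: ConvertedIndex, mode: str, max_mismatches: int):
    """All (chrom_idx, pos, mismatches) with mismatches <= max, via seeds."""
    L = len(query)
    k = index.k
    chroms = list(index.converted[mode])
    arrs = [index.converted[mode][c] for c in chroms]

    n_seg = max_mismatches + 1
    if L < n_seg * k:
        # exhaustive fallback for short reads
        out = []
        for ci, g in enumerate(arrs):
            if len(g) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(g, L)
            mm = (windows != query).sum(axis=1)
            for p in np.flatnonzero(mm <= max_mismatches):
                out.append((ci, int(p), int(mm[p])))
        return out

    qb = query.tobytes()
    seg = L // n_seg
    cand: set[tuple[int, int]] = set()
    seeds = index.seeds[mode]
    for s in range(n_seg):
        off = s * seg
        locs = seeds.get(qb[off : off + k])
        if locs is None:
            continue
        for ci, p in locs:
            start = p - off
            if start >= 0 and start + L <= len(arrs[ci]):
                cand.add((int(ci), int(start)))

    out = []
    for ci, p in cand:
        mm = int(np.count_nonzero(arrs[ci][p : p + L] != query))
        if mm <= max_mismatches:
            out.append((ci, p, mm))
    return out


def _orient(read: np.ndarray, mate: int, hypothesis: str) -> np.ndarray:
    """Plus-strand-oriented original read under a template-strand hypothesis."""
    forward = (mate == 1) == (hypothesis == "+")
    return read if forward else sq.revcomp(read)


def align_read(
    read_id: str,
    seq: str | np.ndarray,
    index: ConvertedIndex,
    mate: int = 1,
    max_mismatches: int = 2,
    max_hits: int = 10,
    rng: np.random.Generator | None = None,
) -> AlignmentHit | None:
    """Place one read on the genome, or return None (discard).

    ``mate`` declares the library orientation: mate 1 reads the bisulfite
    template strand, mate 2 its complement; this decides which conversion
    each strand hypothesis applies. Hits from both hypotheses compete on
    mismatch count; ties are resolved by a uniform draw over the hits
    sorted by (chromosome, position), reproducible under ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    read = sq.encode(seq) if isinstance(seq, str) else seq
    if len(read) < index.k:
        logger.debug("read %s shorter than seed k; discarded", read_id)
        return None

    chroms = list(index.converted["CT"])
    best: list[tuple[int, int, str]] = []
    best_mm = max_mismatches + 1
    for hyp, mode, conv in (("+", "CT", sq.convert_ct), ("-", "GA", sq.convert_ga)):
        oriented = _orient(read, mate, hyp)
        query = conv(oriented)
        for ci, p, mm in _candidate_hits(query, index, mode, max_mismatches):
            if mm < best_mm:
                best_mm = mm
                best = [(ci, p, hyp)]
            elif mm == best_mm:
                best.append((ci, p, hyp))

    if not best or len(best) > max_hits:
        return None
    best.sort()
    ci, p, hyp = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
    return AlignmentHit(
        read_id=read_id,
        chrom=chroms[ci],
        start=p,
        strand=hyp,
        mismatches=best_mm,
        multiplicity=len(best),
        oriented_seq=_orient(read, mate, hyp),
    )


def align_reads(
    reads1,
    reads2=None,
    index: ConvertedIndex | None = None,
    max_mismatches: int = 2,
    max_hits: int = 10,
    seed: int = 0,
) -> list[AlignmentHit]:
    """Align mate-1 and mate-2 read lists; returns kept hits in input order."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 7])
    hits = []
    for mate, reads in ((1, reads1), (2, reads2 or [])):
        for name, seq in reads:
            h = align_read(name, seq, index, mate=mate, max_mismatches=max_mismatches,
                           max_hits=max_hits, rng=rng)
            if h is not None:
                hits.append(h)
    return hits


def dedupe_mate_overlaps(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Mask mate-2 bases that overlap mate 1 of the same pair (first mate wins).

    Pairs are recognised by the ``/1``/``/2`` read-name suffix; overlap only
    matters when both mates landed on the same chromosome and template
    strand.
    """
    mate1: dict[str, AlignmentHit] = {}
    for h in hits:
        if h.read_id.endswith("/1"):
            mate1[h.read_id[:-2]] = h
    for h in hits:
        if not h.read_id.endswith("/2"):
            continue
        m1 = mate1.get(h.read_id[:-2])
        if m1 is None or m1.chrom != h.chrom or m1.strand != h.strand:
            continue
        lo = max(h.start, m1.start)
        hi = min(h.end, m1.end)
        if lo < hi:
            h.exclude = (lo, hi)
    return hits


class Pileup:
    """Per-position bisulfite evidence accumulated over aligned reads."""

    def __init__(self, genome: GenomeBundle):
        self.genome = genome
        self.nC_plus = {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.seqs.items()}
        self.nT_plus = {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.seqs.items()}
        self.nC_minus = {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.seqs.items()}
        self.nT_minus = {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.seqs.items()}

    def add(self, hit: AlignmentHit) -> None:
        g = self.genome.seqs[hit.chrom]
        r = hit.oriented_seq
        start, end = hit.start, hit.start + len(r)
        if start < 0 or end > len(g):
            raise ValueError(f"hit {hit.read_id} at {hit.chrom}:{start}-{end} out of bounds")
        gslice = g[start:end]
        keep = np.ones(len(r), dtype=bool)
        if hit.exclude is not None:
            keep[max(0, hit.exclude[0] - start) : max(0, hit.exclude[1] - start)] = False
        if hit.strand == "+":
            cmask = (gslice == sq.C) & keep
            idx = start + np.flatnonzero(cmask)
            rb = r[cmask]
            np.add.at(self.nC_plus[hit.chrom], idx[rb == sq.C], 1)
            np.add.at(self.nT_plus[hit.chrom], idx[rb == sq.T], 1)
        else:
            gmask = (gslice == sq.G) & keep
            idx = start + np.flatnonzero(gmask)
            rb = r[gmask]
            np.add.at(self.nC_minus[hit.chrom], idx[rb == sq.G], 1)
            np.add.at(self.nT_minus[hit.chrom], idx[rb == sq.A], 1)

    def to_records(self, emit_all: bool = False) -> pd.DataFrame:
        """Per-cytosine table: chrom, pos, strand, context, n_C, n_T."""
        rows = []
        for chrom, seq in self.genome.seqs.items():
            ctxp, ctxm = context_arrays(seq)
            for strand, nc, nt, ctx, base in (
                ("+", self.nC_plus[chrom], self.nT_plus[chrom], ctxp, sq.C),
                ("-", self.nC_minus[chrom], self.nT_minus[chrom], ctxm, sq.G),
            ):
                if emit_all:
                    pos = np.flatnonzero(seq == base)
                else:
                    pos = np.flatnonzero((nc + nt) > 0)
                codes = ctx[pos]
                ok = codes >= 0  # edge/N cytosines carry no context; dropped
                pos = pos[ok]
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "strand": strand,
                            "context": pd.Categorical.from_codes(
                                codes[ok], categories=["CG", "CHG", "CHH"]
                            ),
                            "n_C": nc[pos],
                            "n_T": nt[pos],
                        }
                    )
                )
        df = pd.concat(rows, ignore_index=True)
        return df.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def pileup_cytosines(
    hits: list[AlignmentHit], genome: GenomeBundle, emit_all: bool = False
) -> pd.DataFrame:
    """Count C/T evidence at every covered cytosine from original read bases.

    Evidence comes from the unconverted read: at a plus-strand C a read
    base C counts as methylated and T as unmethylated (G/A analogously on
    the minus strand); any other base there (a sequencing error) is
    ignored. With ``emit_all`` uncovered cytosines are emitted with zero
    counts.
    """
    pile = Pileup(genome)
    for h in hits:
        pile.add(h)
    return pile.to_records(emit_all=emit_all)


def records_with_trinucleotide(records: pd.DataFrame, genome: GenomeBundle) -> pd.DataFrame:
    """Append the strandwise trinucleotide column (for CX-style export)."""
    out = records.copy()
    out["trinucleotide"] = [
        trinucleotide(genome, c, int(p), s)
        for c, p, s in zip(out["chrom"], out["pos"], out["strand"])
    ]
    return out
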