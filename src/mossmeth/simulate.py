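"""Synthetic moss-like genomes, methylomes, bisulfite reads and expression
counts with known ground truth.

The generator emulates a TE-rich genome organised into two chromatin
compartments: heterochromatic blocks (elevated GC, high nucleosome/H3K9me2
signal, densely packed TEs) and euchromatic blocks (low GC, genes plus
scattered TEs). Wild-type methylation concentrates in TEs: high and similar
CG and CHG (default 0.80), moderate CHH in heterochromatic TEs (0.30) and
low CHH in euchromatic TEs (0.08). The mutant methylome applies a strong
multiplicative reduction to the symmetric contexts everywhere, a partial
CHH reduction restricted to heterochromatic TEs, and an additive CHH gain
("redistribution") in euchromatic TE windows whose wild-type CHH mean is
below a low-methylation threshold (default 0.15).

Window-level methylation states are drawn comonotonically across contexts:
each 50-bp window gets one uniform quantile mapped through a per-context
Beta inverse CDF, so contexts with identical target levels receive
identical window levels (a shared local chromatin state), with independent
per-cytosine jitter on top. All generators are pure functions of
``(params, seed)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import _sequtils as sq
from . import io as mio
from .calling import CTX_CG, CTX_CHG, CTX_CHH, context_arrays
from .genome import EU_TE, GENE, HET_TE, INTERGENIC, TRACK_BIN, COMPARTMENT_NAMES, GenomeBundle

METH_WINDOW = 50  # bp; window grain for methylation-state draws

_FAMILIES = {
    "LTR": ("Gypsy1", "Gypsy2", "Copia1"),
    "LINE": ("LINE1",),
    "DNA": ("DNA1", "Helitron1"),
}


class PackingError(ValueError):
    """Requested feature density cannot be placed on the genome."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic study system.

    Probabilities and fractions are in [0, 1]; lengths in bp. The defaults
    describe the simulated wild-type/mutant contrast: TE methylation near
    0.8 in both symmetric contexts, mutant reductions of 76.7% (CG), 77.8%
    (CHG) and 24.1% (CHH in heterochromatin), and a CHH gain of 0.10 in
    lowly methylated euchromatic TE windows.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 250_000
    te_density: float = 0.40
    frac_hetero_te: float = 0.70
    gene_density: float = 0.20
    wt_levels: tuple[float, float, float] = (0.80, 0.80, 0.30)  # CG, CHG, CHH(het)
    wt_chh_euchromatic: float = 0.08
    gene_cg_level: float = 0.05
    background_level: float = 0.02
    mutant_reduction: tuple[float, float, float] = (0.767, 0.778, 0.241)
    chh_hyper_gain: float = 0.10
    low_meth_threshold: float = 0.15
    window_concentration: float = 40.0  # Beta concentration of window states
    site_sd: float = 0.05  # per-cytosine jitter (s.d.)
    conversion_rate: float = 1.0
    meth_protection: float = 1.0
    read_length: int = 100
    coverage: float = 30.0
    seq_error: float = 0.0
    te_mean_length: int = 2000
    gene_mean_length: int = 1500
    n_reps: int = 3
    n_upregulated_te: int = 35
    de_fold: float = 8.0
    nb_dispersion: float = 0.10
    predisposed_base_mean: float = 20.0
    predisposed_ltr_scale: float = 0.15  # WT methylation multiplier in predisposed LTRs

    def validate(self) -> None:
        probs = {
            "te_density": self.te_density,
            "frac_hetero_te": self.frac_hetero_te,
            "gene_density": self.gene_density,
            "wt_chh_euchromatic": self.wt_chh_euchromatic,
            "gene_cg_level": self.gene_cg_level,
            "background_level": self.background_level,
            "chh_hyper_gain": self.chh_hyper_gain,
            "low_meth_threshold": self.low_meth_threshold,
            "conversion_rate": self.conversion_rate,
            "meth_protection": self.meth_protection,
            "seq_error": self.seq_error,
            "predisposed_ltr_scale": self.predisposed_ltr_scale,
        }
        probs.update({f"wt_levels[{i}]": v for i, v in enumerate(self.wt_levels)})
        probs.update({f"mutant_reduction[{i}]": v for i, v in enumerate(self.mutant_reduction)})
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name, v in {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "read_length": self.read_length,
            "te_mean_length": self.te_mean_length,
            "gene_mean_length": self.gene_mean_length,
            "n_reps": self.n_reps,
        }.items():
            if v < 1:
                raise ValueError(f"{name}={v} must be positive")
        if self.coverage < 0 or self.de_fold <= 0 or self.nb_dispersion < 0:
            raise ValueError("coverage must be >= 0, de_fold > 0, nb_dispersion >= 0")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


def _rng(params: SimParams, stream: int, label: str = "") -> np.random.Generator:
    salt = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng([params.seed & 0x7FFFFFFF, stream, salt])


# ---------------------------------------------------------------------------
# genome


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.array([sq.A, sq.C, sq.G, sq.T], dtype=np.uint8)[rng.choice(4, size=n, p=p)]


def _draw_te(rng, params: SimParams, max_len: int):
    length = int(rng.uniform(0.5, 1.5) * params.te_mean_length)
    length = min(max(length, 200), max_len)
    te_class = "LTR" if rng.random() < 0.30 else ("LINE" if rng.random() < 0.5 else "DNA")
    family = _FAMILIES[te_class][rng.integers(len(_FAMILIES[te_class]))]
    strand = "+" if rng.random() < 0.5 else "-"
    return length, te_class, family, strand


def simulate_genome(params: SimParams) -> GenomeBundle:
    """Generate a genome with compartmentalised TE and gene annotations.

    Heterochromatic blocks are elevated-GC segments densely packed with
    TEs; euchromatic blocks carry genes and the remaining TEs at low GC.
    LTR-class TEs get two terminal LTR sub-intervals (15% of the element
    per side). A deterministic subset of euchromatic LTR TEs is flagged
    ``predisposed`` (the TEs the expression simulator will upregulate and
    the methylome simulator will deplete of LTR methylation).
    """
    params.validate()
    rng = _rng(params, 1)

    het_te_target = params.te_density * params.frac_hetero_te
    het_block_frac = het_te_target / 0.80  # hetero blocks are ~80% TE
    eu_needed = params.te_density * (1 - params.frac_hetero_te) + params.gene_density
    if het_block_frac > 0.85 or eu_needed > 0.80 * (1 - het_block_frac):
        raise PackingError(
            f"te_density={params.te_density} with gene_density={params.gene_density} "
            "cannot be packed; lower the densities"
        )

    seqs: dict[str, np.ndarray] = {}
    genes, tes = [], []
    het_masks: dict[str, np.ndarray] = {}

    for ci in range(params.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = params.chrom_length
        het_total = int(het_block_frac * L)
        n_blocks = max(1, int(round(het_total / 30_000))) if het_total > 0 else 0

        # alternate euchromatic / heterochromatic segments
        het_lens = (
            np.maximum(1, rng.multinomial(het_total, np.ones(n_blocks) / n_blocks))
            if n_blocks
            else np.array([], dtype=int)
        )
        eu_total = L - int(het_lens.sum())
        eu_lens = np.maximum(1, rng.multinomial(eu_total, np.ones(n_blocks + 1) / (n_blocks + 1)))

        seq = np.empty(L, dtype=np.uint8)
        het_mask = np.zeros(L, dtype=bool)
        pos = 0
        segments = []  # (start, end, is_het)
        for b in range(n_blocks + 1):
            e = min(pos + int(eu_lens[b]), L)
            if b == n_blocks:
                e = L  # last euchromatic segment absorbs rounding slack
            if e > pos:
                segments.append((pos, e, False))
            pos = e
            if b < n_blocks:
                e = min(pos + int(het_lens[b]), L)
                if e > pos:
                    segments.append((pos, e, True))
                pos = e
        for s, e, is_het in segments:
            gc = rng.normal(0.55 if is_het else 0.35, 0.02)
            seq[s:e] = _random_bases(rng, e - s, float(np.clip(gc, 0.2, 0.8)))
            het_mask[s:e] = is_het

        # pack heterochromatic blocks with TEs
        for s, e, is_het in segments:
            if not is_het:
                continue
            cur = s + int(rng.integers(20, 150))
            while cur < e - 250:
                length, te_class, family, strand = _draw_te(rng, params, e - cur)
                tes.append((chrom, cur, cur + length, strand, family, te_class, "heterochromatic"))
                cur += length + int(rng.integers(20, 200))

        # euchromatic blocks: genes plus the remaining TEs
        eu_te_target = int(params.te_density * (1 - params.frac_hetero_te) * L)
        gene_target = int(params.gene_density * L)
        te_placed = gene_placed = 0
        for s, e, is_het in segments:
            if is_het:
                continue
            cur = s + int(rng.integers(50, 300))
            while cur < e - 300:
                want_te = te_placed < eu_te_target and (
                    gene_placed >= gene_target or rng.random() < 0.4
                )
                if want_te:
                    length, te_class, family, strand = _draw_te(rng, params, e - cur)
                    tes.append((chrom, cur, cur + length, strand, family, te_class, "euchromatic"))
                    te_placed += length
                    cur += length + int(rng.integers(50, 300))
                elif gene_placed < gene_target:
                    length = int(rng.uniform(0.5, 1.5) * params.gene_mean_length)
                    length = min(max(length, 300), e - cur)
                    strand = "+" if rng.random() < 0.5 else "-"
                    genes.append((chrom, cur, cur + length, strand))
                    gene_placed += length
                    cur += length + int(rng.integers(50, 300))
                else:
                    break

        seqs[chrom] = seq
        het_masks[chrom] = het_mask

    tes_df = pd.DataFrame(
        tes, columns=["chrom", "start", "end", "strand", "family", "te_class", "compartment"]
    )
    tes_df = tes_df.astype({"start": np.int64, "end": np.int64})
    tes_df["name"] = [f"TE{i + 1:05d}" for i in range(len(tes_df))]
    for col in ("ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end"):
        tes_df[col] = np.nan
    is_ltr = tes_df["te_class"] == "LTR"
    ltr_len = ((tes_df["end"] - tes_df["start"]) * 0.15).round().astype(int)
    tes_df.loc[is_ltr, "ltr5_start"] = tes_df.loc[is_ltr, "start"]
    tes_df.loc[is_ltr, "ltr5_end"] = tes_df.loc[is_ltr, "start"] + ltr_len[is_ltr]
    tes_df.loc[is_ltr, "ltr3_start"] = tes_df.loc[is_ltr, "end"] - ltr_len[is_ltr]
    tes_df.loc[is_ltr, "ltr3_end"] = tes_df.loc[is_ltr, "end"]

    # predisposed set: euchromatic LTR TEs first, then any remaining TEs
    tes_df["predisposed"] = False
    pool = tes_df.index[(tes_df["te_class"] == "LTR") & (tes_df["compartment"] == "euchromatic")]
    if len(pool) < params.n_upregulated_te:
        extra = tes_df.index.difference(pool)
        pool = pool.append(extra[: params.n_upregulated_te - len(pool)])
    n_pick = min(params.n_upregulated_te, len(pool))
    if n_pick:
        chosen = rng.choice(np.asarray(pool), size=n_pick, replace=False)
        tes_df.loc[chosen, "predisposed"] = True

    genes_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "strand"])
    genes_df["name"] = [f"G{i + 1:05d}" for i in range(len(genes_df))]

    tracks = _chromatin_tracks(seqs, het_masks, rng)
    bundle = GenomeBundle(seqs=seqs, genes=genes_df, tes=tes_df, tracks=tracks)
    return bundle


def _chromatin_tracks(seqs, het_masks, rng) -> pd.DataFrame:
    frames = []
    for chrom, seq in seqs.items():
        L = len(seq)
        starts = np.arange(0, L, TRACK_BIN)
        ends = np.minimum(starts + TRACK_BIN, L)
        gcmask = (seq == sq.G) | (seq == sq.C)
        cg = np.concatenate([[0], np.cumsum(gcmask)])
        gc = (cg[ends] - cg[starts]) / (ends - starts)
        ch = np.concatenate([[0], np.cumsum(het_masks[chrom])])
        het_frac = (ch[ends] - ch[starts]) / (ends - starts)
        h3 = np.clip(0.30 + 0.50 * het_frac + rng.normal(0, 0.05, len(starts)), 0, 1)
        k9 = np.clip(0.10 + 0.70 * het_frac + rng.normal(0, 0.05, len(starts)), 0, 1)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "gc": gc, "h3": h3, "h3k9me2": k9}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# methylomes


@dataclass
class GroundTruthMethylome:
    """True per-cytosine methylation probabilities for one sample.

    ``p_plus[chrom][i]`` is defined (non-NaN) exactly at plus-strand C
    positions and ``p_minus[chrom][i]`` at plus-strand G positions (a C on
    the minus strand).
    """

    p_plus: dict[str, np.ndarray]
    p_minus: dict[str, np.ndarray]
    genome: GenomeBundle

    def n_records(self) -> int:
        return int(
            sum(np.isfinite(a).sum() for a in self.p_plus.values())
            + sum(np.isfinite(a).sum() for a in self.p_minus.values())
        )

    def to_frame(self) -> pd.DataFrame:
        """Long table: chrom, pos (0-based), strand, context, compartment, p_meth."""
        rows = []
        for chrom, seq in self.genome.seqs.items():
            ctxp, ctxm = context_arrays(seq)
            comp = self.genome.compartment_arrays[chrom]
            for strand, parr, ctx in (("+", self.p_plus[chrom], ctxp), ("-", self.p_minus[chrom], ctxm)):
                pos = np.flatnonzero(np.isfinite(parr))
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "strand": strand,
                            "context": pd.Categorical.from_codes(
                                np.where(ctx[pos] >= 0, ctx[pos], 3),
                                categories=["CG", "CHG", "CHH", "undefined"],
                            ),
                            "compartment": pd.Categorical.from_codes(
                                comp[pos], categories=[COMPARTMENT_NAMES[i] for i in range(4)]
                            ),
                            "p_meth": parr[pos],
                        }
                    )
                )
        df = pd.concat(rows, ignore_index=True)
        return df.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def _wt_level_table(params: SimParams) -> np.ndarray:
    """Mean WT methylation by (compartment, context)."""
    mu = np.zeros((4, 3))
    mu[INTERGENIC] = params.background_level
    mu[GENE] = (params.gene_cg_level, params.background_level, params.background_level)
    mu[EU_TE] = (params.wt_levels[0], params.wt_levels[1], params.wt_chh_euchromatic)
    mu[HET_TE] = params.wt_levels
    return mu


def simulate_methylomes(
    bundle: GenomeBundle, params: SimParams
) -> tuple[GroundTruthMethylome, GroundTruthMethylome]:
    """Draw matched wild-type and mutant per-cytosine methylation truths.

    The mutant is derived from the wild type site-by-site: CG and CHG
    probabilities are scaled by ``1 - mutant_reduction`` everywhere, CHH is
    scaled only in heterochromatic TEs, and euchromatic-TE CHH positions in
    windows whose wild-type CHH mean is below ``low_meth_threshold`` gain
    ``chh_hyper_gain`` (clipped to 1).
    """
    params.validate()
    rng = _rng(params, 2)
    mu_table = _wt_level_table(params)
    conc = params.window_concentration

    wt_p, wt_m, mut_p, mut_m = {}, {}, {}, {}
    for chrom, seq in bundle.seqs.items():
        L = len(seq)
        ctxp, ctxm = context_arrays(seq)
        comp = bundle.compartment_arrays[chrom]
        n_win = -(-L // METH_WINDOW)
        q = rng.uniform(size=n_win)

        # per-site WT draw; ppf evaluated once per distinct level per window
        def draw(parr_mask: np.ndarray, ctx: np.ndarray) -> np.ndarray:
            out = np.full(L, np.nan)
            pos = np.flatnonzero(parr_mask)
            if len(pos) == 0:
                return out
            ctx_eff = np.where(ctx[pos] >= 0, ctx[pos], CTX_CHH)  # edge sites: CHH-like
            mus = mu_table[comp[pos], ctx_eff]
            base = np.empty(len(pos))
            for mu in np.unique(mus):
                sel = mus == mu
                if mu <= 0.0 or mu >= 1.0:
                    base[sel] = mu
                    continue
                ppf = stats.beta.ppf(q, mu * conc, (1 - mu) * conc)
                base[sel] = ppf[pos[sel] // METH_WINDOW]
                jitter = rng.normal(0, params.site_sd, int(sel.sum()))
                base[sel] = np.clip(base[sel] + jitter, 0.0, 1.0)
            out[pos] = base
            return out

        wt_p[chrom] = draw(seq == sq.C, ctxp)
        wt_m[chrom] = draw(seq == sq.G, ctxm)

        # predisposed TEs: methylation-depleted LTR sub-intervals in WT
        pre = bundle.tes[
            (bundle.tes["chrom"] == chrom)
            & bundle.tes["predisposed"]
            & bundle.tes["ltr5_start"].notna()
        ]
        for _, te in pre.iterrows():
            for lo, hi in ((te["ltr5_start"], te["ltr5_end"]), (te["ltr3_start"], te["ltr3_end"])):
                sl = slice(int(lo), int(hi))
                wt_p[chrom][sl] *= params.predisposed_ltr_scale
                wt_m[chrom][sl] *= params.predisposed_ltr_scale

        # mutant: derived site-by-site from WT
        r_cg, r_chg, r_chh = params.mutant_reduction
        mp = wt_p[chrom].copy()
        mm = wt_m[chrom].copy()
        for arr, ctx in ((mp, ctxp), (mm, ctxm)):
            arr[ctx == CTX_CG] *= 1 - r_cg
            arr[ctx == CTX_CHG] *= 1 - r_chg
            arr[(ctx == CTX_CHH) & (comp == HET_TE)] *= 1 - r_chh

        # CHH redistribution: gain in lowly methylated euchromatic TE windows
        if params.chh_hyper_gain > 0:
            widx = np.arange(L) // METH_WINDOW
            chh_mask_p = ctxp == CTX_CHH
            chh_mask_m = ctxm == CTX_CHH
            num = np.bincount(widx[chh_mask_p], np.nan_to_num(wt_p[chrom][chh_mask_p]), n_win)
            num += np.bincount(widx[chh_mask_m], np.nan_to_num(wt_m[chrom][chh_mask_m]), n_win)
            den = np.bincount(widx[chh_mask_p], minlength=n_win) + np.bincount(
                widx[chh_mask_m], minlength=n_win
            )
            with np.errstate(invalid="ignore"):
                win_mean = np.where(den > 0, num / np.maximum(den, 1), np.nan)
            low_win = win_mean < params.low_meth_threshold
            for arr, ctx in ((mp, ctxp), (mm, ctxm)):
                gain = (ctx == CTX_CHH) & (comp == EU_TE) & low_win[widx]
                arr[gain] = np.minimum(arr[gain] + params.chh_hyper_gain, 1.0)

        mut_p[chrom] = mp
        mut_m[chrom] = mm

    wt = GroundTruthMethylome(wt_p, wt_m, bundle)
    mut = GroundTruthMethylome(mut_p, mut_m, bundle)
    return wt, mut


# ---------------------------------------------------------------------------
# bisulfite reads


def simulate_bisulfite_reads(
    bundle: GenomeBundle,
    truth: GroundTruthMethylome,
    params: SimParams,
    sample: str = "sample",
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Simulate a directional paired-end bisulfite library.

    The number of pairs is ``round(coverage * genome_length /
    (2 * read_length))``. Fragments are drawn uniformly over chromosomes
    (weighted by length) and strands; mate 1 reads the bisulfite template
    strand 5'->3' and mate 2 the complementary strand. Each templated
    cytosine is methylated by a Bernoulli draw under its true probability;
    methylated cytosines read C with probability ``meth_protection``,
    unmethylated ones read T with probability ``conversion_rate``.
    Independent sequencing errors are applied last. Read names encode the
    true origin: ``sample|chrom|fragment_start|fragment_len|strand|index``.
    """
    params.validate()
    if params.coverage <= 0:
        raise ValueError("coverage must be > 0")
    rl = params.read_length
    for chrom, seq in bundle.seqs.items():
        if rl > len(seq):
            raise ValueError(f"read_length {rl} exceeds length of {chrom}")

    rng = _rng(params, 3, sample)
    chroms = bundle.chroms
    lengths = np.array([bundle.chrom_length(c) for c in chroms], dtype=float)
    total = lengths.sum()
    n_pairs = int(round(params.coverage * total / (2 * rl)))

    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=lengths / total)
    strands = np.where(rng.random(n_pairs) < 0.5, "+", "-")
    gaps = rng.integers(20, 121, size=n_pairs)

    bases = np.array([sq.A, sq.C, sq.G, sq.T], dtype=np.uint8)
    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    for i in range(n_pairs):
        chrom = chroms[chrom_idx[i]]
        L = int(lengths[chrom_idx[i]])
        frag_len = min(2 * rl + int(gaps[i]), L)
        start = int(rng.integers(0, L - frag_len + 1))
        strand = strands[i]
        frag = bundle.seqs[chrom][start : start + frag_len].copy()

        if strand == "+":
            cpos = np.flatnonzero(frag == sq.C)
            p = truth.p_plus[chrom][start + cpos]
            unconverted_base = sq.T
        else:
            cpos = np.flatnonzero(frag == sq.G)
            p = truth.p_minus[chrom][start + cpos]
            unconverted_base = sq.A
        if len(cpos):
            meth = rng.random(len(cpos)) < p
            u = rng.random(len(cpos))
            shows_c = np.where(meth, u < params.meth_protection, u >= params.conversion_rate)
            frag[cpos[~shows_c]] = unconverted_base

        if strand == "+":
            m1, m2 = frag[:rl].copy(), sq.revcomp(frag[-rl:])
        else:
            m1, m2 = sq.revcomp(frag[-rl:]), frag[:rl].copy()

        if params.seq_error > 0:
            for m in (m1, m2):
                err = np.flatnonzero(rng.random(rl) < params.seq_error)
                if len(err):
                    m[err] = bases[rng.integers(0, 4, len(err))]

        name = f"{sample}|{chrom}|{start}|{frag_len}|{strand}|{i}"
        reads1.append((name + "/1", sq.decode(m1)))
        reads2.append((name + "/2", sq.decode(m2)))
    return reads1, reads2


# ---------------------------------------------------------------------------
# expression counts


def simulate_expression_counts(bundle: GenomeBundle, params: SimParams):
    """Negative-binomial gene/TE expression counts for two genotypes.

    Genes draw lognormal baseline means; TEs are near-silent except the
    ``predisposed`` set, which gets a small nonzero wild-type mean and a
    ``de_fold``-times-higher mean in the mutant. Returns ``(CountMatrix,
    truth)`` where truth lists the truly differential features (empty when
    ``de_fold == 1``).
    """
    from .expression import CountMatrix  # local import: no cycle at module load

    params.validate()
    if params.n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = _rng(params, 4)

    feats = []
    for _, row in bundle.genes.iterrows():
        feats.append((row["name"], "gene", "", False))
    for _, row in bundle.tes.iterrows():
        feats.append((row["name"], "te", row["family"], bool(row["predisposed"])))
    meta = pd.DataFrame(feats, columns=["feature", "kind", "family", "predisposed"]).set_index(
        "feature"
    )

    n = len(meta)
    base = np.where(
        meta["kind"] == "gene",
        rng.lognormal(np.log(150), 1.0, n),
        rng.lognormal(np.log(4.0), 1.0, n),
    )
    base = np.where(meta["predisposed"], params.predisposed_base_mean, base)
    mut_mean = np.where(meta["predisposed"], base * params.de_fold, base)

    disp = params.nb_dispersion
    cols, data, genotypes = [], [], {}
    for g, means in (("wt", base), ("mut", mut_mean)):
        for r in range(params.n_reps):
            col = f"{g}_{r + 1}"
            if disp > 0:
                nb_n = 1.0 / disp
                nb_p = nb_n / (nb_n + means)
                counts = rng.negative_binomial(nb_n, nb_p)
            else:
                counts = rng.poisson(means)
            cols.append(col)
            data.append(counts)
            genotypes[col] = g
    counts = pd.DataFrame(np.column_stack(data), index=meta.index, columns=cols)

    if params.de_fold != 1:
        truth = pd.DataFrame(
            {
                "feature": meta.index[meta["predisposed"]],
                "true_fold": params.de_fold,
                "direction": "up" if params.de_fold > 1 else "down",
            }
        ).reset_index(drop=True)
    else:
        truth = pd.DataFrame(columns=["feature", "true_fold", "direction"])

    return CountMatrix(counts=counts, meta=meta, genotypes=genotypes), truth


# ---------------------------------------------------------------------------
# writers


def write_bundle(bundle: GenomeBundle, outdir) -> dict[str, Path]:
    """Write the genome bundle to standard text formats; returns paths."""
    out = mio.ensure_dir(outdir)
    paths = {"genome": out / "genome.fa"}
    mio.write_fasta(paths["genome"], bundle.seqs)
    paths["genes_bed"] = out / "genes.bed"
    genes = bundle.genes.assign(family="gene", klass="gene")
    mio.write_bed(paths["genes_bed"], genes.assign(name=genes["name"]))
    paths["tes_bed"] = out / "tes.bed"
    tes = bundle.tes.assign(name=bundle.tes["family"] + ":" + bundle.tes["te_class"])
    mio.write_bed(paths["tes_bed"], tes)
    paths["genes_gff"] = out / "genes.gff3"
    mio.write_gff3(paths["genes_gff"], bundle.genes, "mossmeth-sim", "gene")
    paths["tes_gff"] = out / "tes.gff3"
    mio.write_gff3(paths["tes_gff"], bundle.tes, "mossmeth-sim", "transposable_element")
    for track in ("gc", "h3", "h3k9me2"):
        paths[track] = out / f"{track}.bedgraph"
        mio.write_bedgraph(paths[track], bundle.tracks, track)
    return paths


def write_truth(truth: GroundTruthMethylome, path) -> None:
    mio.write_tsv(path, truth.to_frame())
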