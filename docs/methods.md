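# Methods

This note documents the models, parameter choices and numerical
conventions behind `mossmeth`, and what the synthetic study can and cannot
say about real data.

## The synthetic study system

The generator (`mossmeth.simulate`) emulates a TE-rich plant genome with
two chromatin compartments:

- **Heterochromatic blocks**: elevated GC (≈0.55), high nucleosome (H3)
  and H3K9me2 track values, densely packed with TEs (~80% of block
  length). By default 70% of TE sequence lives here (`frac_hetero_te`).
- **Euchromatic blocks**: low GC (≈0.35), genes plus scattered TEs.

Chromatin tracks are emitted per 50 bp: GC is computed from the actual
simulated sequence; H3 and H3K9me2 are compartment-driven proxies with
Gaussian noise, so they correlate with — but do not duplicate — the
compartment labels.

TEs carry family labels; 30% are LTR-class with two terminal LTR
sub-intervals of 15% of the element length per side (both proportions are
modelling choices, not measured values). A configurable subset of
euchromatic LTR TEs is flagged **predisposed**: their LTRs are
methylation-depleted in the wild type (`predisposed_ltr_scale`, default
0.15×) and they carry small nonzero baseline expression — the structure
the upregulated-TE contrast is designed to recover.

### Methylome model

Wild-type per-cytosine methylation probabilities are drawn hierarchically:

1. Each 50-bp window receives one uniform quantile `q`.
2. For every (compartment, context) mean level μ, the window level is the
   Beta(μ·κ, (1−μ)·κ) inverse CDF at `q` (concentration κ =
   `window_concentration`, default 40). Because all contexts share the
   window's quantile (a comonotonic draw), contexts with equal target
   levels get equal window levels — modelling a shared local chromatin
   state. This is what makes the matched-window mCG−mCHG median a sharp
   null: when CG and CHG are configured equal, their per-window levels are
   identical and the observed difference is pure counting noise.
3. Independent per-cytosine Gaussian jitter (s.d. `site_sd` = 0.05),
   clipped to [0, 1]. Degenerate levels (μ = 0 or 1) stay exactly 0 or 1
   so calibration bounds are exact.

Default mean levels: TE CG = CHG = 0.80 in both compartments; CHH = 0.30
in heterochromatic TEs and 0.08 in euchromatic TEs (so euchromatic TE
windows sit below the 0.15 low-methylation threshold); gene-body CG = 0.05
(CG-only); background 0.02. The split CHH default reflects the observed
regime in DDM1-type mutants, where hyper-methylation concentrates in
sequence with wild-type CHH below ~15% and hypo-methylation in the
~23–47% band.

The mutant methylome is derived site-by-site from the wild type:

- CG and CHG: multiplied by (1 − reduction) everywhere (defaults 0.767 and
  0.778).
- CHH: multiplied by (1 − 0.241) in heterochromatic TEs only.
- CHH redistribution: euchromatic TE positions whose wild-type window CHH
  mean is below `low_meth_threshold` (0.15) gain `chh_hyper_gain` (0.10),
  clipped at 1.

A consequence worth noting: the *net* TE-wide CHH reduction measured by
the pipeline (~13%) is smaller than the configured heterochromatic
reduction (24.1%) because the euchromatic gain partially offsets it. The
clean parameter-recovery checks therefore use `frac_hetero_te = 1` and
`chh_hyper_gain = 0`, under which all three reductions are recovered
within a fraction of a percentage point at 30×.

### Bisulfite library model

Directional paired-end libraries: mate 1 reads the bisulfite template
strand 5′→3′, mate 2 the complementary strand. The number of pairs is
`round(coverage · genome / (2 · read_length))`. Each templated cytosine is
methylated by a Bernoulli draw under its true probability; methylated
cytosines read C with probability `meth_protection`, unmethylated ones
read T with probability `conversion_rate`. Both default to 1 and
`seq_error` defaults to 0, keeping oracle tests exact; imperfect chemistry
and errors are opt-in. Mates are non-overlapping by construction (fragment
= 2 reads + a 20–120 bp gap) except on chromosomes too short to fit a
fragment. Read names encode the true origin for bookkeeping oracles. Not
modelled: PCR duplicates, adapter contamination, quality-score structure,
non-directional protocols.

### Expression model

Negative-binomial counts (dispersion 0.10) with lognormal baseline means
(genes: log-mean log 150, σ 1.0; TEs: log 4, σ 1.0 — near-silent but with
enough background transcription that a useful fraction survives the
count ≥ 10 filter). Predisposed TEs get mean 20 in wild type and
mean × `de_fold` (8) in the mutant; the truth table lists exactly this
set (empty when `de_fold` = 1).

## Alignment

Seed-and-extend over the converted genome with a pigeonhole guarantee:
allowing m mismatches, the read is split into m+1 segments, at least one
of which must be exact; each segment's leading 20-mer is looked up in an
exact k-mer index and candidates are verified by full ungapped comparison.
Reads shorter than 3k fall back to an exhaustive scan, so the search is
complete for every read length ≥ k. Both template-strand hypotheses
compete on mismatch count; ties (including the same locus reached under
both conversions, which can happen for C/G-free reads) are pooled, reads
with more than `max_hits` (10) equally good placements are discarded, and
one survivor is drawn uniformly under the run seed from the hits sorted by
(chromosome, position) — reproducible across runs. Indels, local
alignment and quality trimming are out of scope: the simulator emits
ungapped, untrimmed reads.

Multi-hit reads contribute to the pileup through their single chosen
placement. Overlapping mate bases at the same cytosine are counted once
(mate 1 wins). At a cytosine, read bases other than C/T (plus strand) or
G/A (minus strand) are sequencing errors and are ignored.

## Methylation calling conventions

- Context is strandwise: CG if the next base is G, CHG if the base after
  next is G, else CHH. A cytosine whose two downstream bases are not both
  defined (N or off-chromosome) carries no context and is excluded —
  including the CG-like cytosine at the penultimate chromosome position,
  a deliberate strictness so that every labelled site has a full
  trinucleotide.
- Windows default to non-overlapping 50-bp tiles (a sliding step is
  supported); fractions are pooled counts, undefined (NaN) below
  `min_calls` = 4 informative calls.
- A window belongs to a TE when ≥ 50% of it overlaps the element.
- Genome-wide weighted means over non-overlapping windows equal weighted
  means over cytosine records by construction (same denominators).

## Comparative statistics

- Percent change: `100·(m_B − m_A)/max(m_A, m_B)`; 0/0 ≡ 0 (no evidence
  of change); computed as the ratio first so the ±100 boundary is exact in
  floating point. Sign positive = higher in the mutant.
- Matched windows: equal covered CG and CHG site counts (≥1) in both
  samples and max over {mCG, mCHG} × {both samples} > 0.5. The summary
  reports the median and quartiles of per-sample mCG − mCHG.
- Stratification: windows ranked by an attribute (stable sort, so a
  constant attribute yields coordinate-ordered groups) and split into
  `n_quantiles` (default 5) near-equal groups; per-group median,
  quartiles, mean of signed percent change.
- Chromosome profiles: weighted per-context methylation in 100-kb bins
  (tiles by default; a sliding step is available); empty bins are gaps.
- The headline per-context reduction aggregates counts over all
  TE-assigned windows per sample and applies percent change to the two
  aggregate levels.

## Meta-profiles

TEs aligned at the 5′ or 3′ end, strandwise offsets binned at 100 bp by
default (50 bp is the figure-style alternative; both are honoured because
the two conventions coexist in practice). Each element contributes inward
until its own far boundary and outward until the first base of any other
annotated feature (gene or TE), both capped at `max_offset`. Per-offset
values are count-weighted means, so the pooled inside-element profile mass
equals regional methylation over the same truncated footprints exactly.

## Differential expression

CPM normalisation, log2(CPM + 0.5), pooled-variance two-sample t-test,
then the fixed decisive thresholds: summed count ≥ 10 to be tested,
|fold| ≥ 2 and p < 0.05 to be called. The pooled test (rather than the
unequal-variance Welch variant) is a deliberate choice: at three
replicates per genotype Welch's small-sample correction makes it markedly
conservative (empirical size ≈ 0.03 at nominal 0.05), while the pooled
test holds its nominal size on this generator (≈ 0.04–0.055) — and the
simulated genotypes share a common dispersion, satisfying the pooled
test's assumption. The count filter applies to the sum over all
replicates (configurable). Zero variance in both groups yields p = 1 when
means are equal, p = 0 otherwise.

The upregulated-vs-unaffected TE contrast reports group medians of
wild-type whole/internal/LTR methylation and whole-element percent change,
plus a rank-biserial effect size (from a two-sided Mann–Whitney U) on
wild-type LTR methylation.

## Problem sizes and reproducibility

Default desk scale is 2 × 250 kb chromosomes at 30× coverage — chosen so
a full run completes in well under a minute per sample on one CPU while
leaving hundreds of matched windows and TE windows per quantile; test
suites use 30–300 kb instances and the oracle checks use ≤ 10 kb genomes
where exhaustive scanning is feasible. All generators and the aligner's
tie-breaking derive their randomness from explicit seeds; two runs with
one seed produce byte-identical outputs (verified by SHA-256 manifests in
the run report).

## Limitations

Passing tests demonstrate correctness of the computations and
recoverability of the simulated structure — not that real moss data has
this structure. The simulator's sequences are i.i.d. within blocks (no
repeats beyond TE placement, no motif bias), its TE families are labels
rather than homologous sequence, bisulfite chemistry is perfect by
default, and expression counts ignore gene length and transcript
structure. The DE test is a plain t-test, not a moderated model; with
three replicates its power profile differs from shrinkage-based methods.
Cross-species comparisons and DMR segmentation are out of scope.
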