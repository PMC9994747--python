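"""Aligner unit tests: conversion rules, seeded search vs an exhaustive
all-position oracle, and pileup counting semantics."""

import numpy as np
import pandas as pd
import pytest

import mossmeth._sequtils as sq
from mossmeth.align import (
    AlignmentHit,
    align_read,
    align_reads,
    build_converted_index,
    dedupe_mate_overlaps,
    pileup_cytosines,
)
from mossmeth.simulate import simulate_bisulfite_reads, simulate_methylomes

from conftest import make_bundle


def brute_force_best_hits(read, mate, bundle, max_mm=2):
    """All minimum-mismatch placements by scanning every position, both
    strand hypotheses, both conversion modes. Independent of the seeded
    index path."""
    chroms = list(bundle.seqs)
    hits = []
    for hyp, conv in (("+", sq.convert_ct), ("-", sq.convert_ga)):
        oriented = read if (mate == 1) == (hyp == "+") else sq.revcomp(read)
        query = conv(oriented)
        for ci, chrom in enumerate(chroms):
            g = conv(bundle.seqs[chrom])
            if len(g) < len(query):
                continue
            win = np.lib.stride_tricks.sliding_window_view(g, len(query))
            mm = (win != query).sum(axis=1)
            for p in np.flatnonzero(mm <= max_mm):
                hits.append((int(mm[p]), ci, int(p), hyp))
    if not hits:
        return None, []
    best = min(h[0] for h in hits)
    return best, sorted((ci, p, hyp) for m, ci, p, hyp in hits if m == best)


class TestConversion:
    def test_ct_conversion_rule(self):
        assert sq.decode(sq.convert_ct(sq.encode("ACGT"))) == "ATGT"

    def test_ga_conversion_rule(self):
        assert sq.decode(sq.convert_ga(sq.encode("ACGT"))) == "ACAT"

    def test_conversions_idempotent(self):
        s = sq.encode("ACGTNACGT")
        np.testing.assert_array_equal(sq.convert_ct(sq.convert_ct(s)), sq.convert_ct(s))
        np.testing.assert_array_equal(sq.convert_ga(sq.convert_ga(s)), sq.convert_ga(s))

    def test_index_sequences_three_letter(self, tiny_index):
        for arr in tiny_index.converted["CT"].values():
            assert not (arr == sq.C).any()
            assert len(arr) == len(arr)
        for arr in tiny_index.converted["GA"].values():
            assert not (arr == sq.G).any()

    def test_converted_lengths_equal_original(self, tiny_bundle, tiny_index):
        for chrom, s in tiny_bundle.seqs.items():
            assert len(tiny_index.converted["CT"][chrom]) == len(s)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            build_converted_index(make_bundle({}))


class TestAlignRead:
    def test_unique_exact_match_found(self, tiny_bundle, tiny_index):
        chrom = tiny_bundle.chroms[0]
        frag = sq.decode(sq.convert_ct(tiny_bundle.seqs[chrom][1000:1050]))
        hit = align_read("r1", frag, tiny_index, mate=1)
        assert hit is not None
        assert (hit.chrom, hit.start, hit.strand) == (chrom, 1000, "+")
        assert hit.mismatches == 0 and hit.multiplicity == 1

    def test_unmatchable_read_discarded(self, tiny_index):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 80))
        assert align_read("r1", junk, tiny_index) is None
        # a read of pure N can match nothing within 2 mismatches
        assert align_read("rN", "N" * 80, tiny_index) is None

    def test_read_shorter_than_seed_discarded(self, tiny_index):
        assert align_read("tiny", "ACGTACGT", tiny_index) is None

    def test_repeat_beyond_max_hits_discarded(self):
        rng = np.random.default_rng(42)
        unit = "".join(rng.choice(list("ACGT"), 80))  # non-periodic 80 bp unit
        bundle = make_bundle({"chr1": unit * 12})
        index = build_converted_index(bundle)
        hit = align_read("rep", sq.decode(sq.convert_ct(sq.encode(unit))), index, mate=1)
        assert hit is None  # 12 equally good placements > 10
        hit = align_read("rep", sq.decode(sq.convert_ct(sq.encode(unit))), index,
                         mate=1, max_hits=20)
        assert hit is not None and hit.multiplicity >= 12

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        """Seeded pigeonhole search equals an all-position, both-strand,
        both-conversion brute force on a random small genome."""
        rng = np.random.default_rng(seed)
        g = "".join(rng.choice(list("ACGT"), 4000, p=[0.3, 0.2, 0.2, 0.3]))
        bundle = make_bundle({"chrA": g[:2500], "chrB": g[2500:]})
        index = build_converted_index(bundle)
        chroms = bundle.chroms
        for _ in range(40):
            L = int(rng.choice([40, 75, 90]))  # exercises fallback + seeded paths
            ci = int(rng.integers(2))
            src = bundle.seqs[chroms[ci]]
            start = int(rng.integers(0, len(src) - L + 1))
            frag = src[start : start + L].copy()
            strand = "+" if rng.random() < 0.5 else "-"
            mate = int(rng.integers(1, 3))
            # bisulfite-convert with random methylation, then mutate a little
            tpl, conv = (sq.C, sq.T) if strand == "+" else (sq.G, sq.A)
            cpos = np.flatnonzero(frag == tpl)
            flip = cpos[rng.random(len(cpos)) < 0.6]
            frag[flip] = conv
            for _ in range(int(rng.integers(0, 3))):
                frag[rng.integers(L)] = sq.encode("ACGT"[rng.integers(4)])[0]
            forward = (strand == "+") == (mate == 1)
            read = frag[:] if forward else sq.revcomp(frag)

            best_mm, best_set = brute_force_best_hits(read, mate, bundle)
            hit = align_read("r", read, index, mate=mate, rng=np.random.default_rng(1))
            if best_mm is None or len(best_set) > 10:
                assert hit is None
            else:
                assert hit is not None
                assert hit.mismatches == best_mm
                assert hit.multiplicity == len(best_set)
                assert (chroms.index(hit.chrom), hit.start, hit.strand) in best_set


class TestPileup:
    def _one_read_records(self, bundle, seqstr, start, strand="+", mate=1):
        read = sq.encode(seqstr)
        oriented = read if (mate == 1) == (strand == "+") else sq.revcomp(read)
        hit = AlignmentHit("r/1", bundle.chroms[0], start, strand, 0, 1, oriented_seq=oriented)
        return pileup_cytosines([hit], bundle)

    def test_fully_methylated_read_counts_all_c(self):
        g = "ATCGATCGATCGATCGATCGATCG"
        bundle = make_bundle({"chr1": g})
        rec = self._one_read_records(bundle, g, 0)  # unconverted = fully methylated
        plus = rec[rec["strand"] == "+"]
        assert (plus["n_C"] == 1).all() and (plus["n_T"] == 0).all()
        assert len(plus) == g[:-2].count("C")  # edge cytosines lack context

    def test_fully_converted_read_counts_all_t(self):
        g = "ATCGATCGATCGATCGATCGATCG"
        bundle = make_bundle({"chr1": g})
        rec = self._one_read_records(bundle, g.replace("C", "T"), 0)
        plus = rec[rec["strand"] == "+"]
        assert (plus["n_T"] == 1).all() and (plus["n_C"] == 0).all()

    def test_sequencing_error_base_ignored(self):
        g = "AACGTACGTACG"
        bundle = make_bundle({"chr1": g})
        bad = "AAGGTACGTACG"  # C at pos 2 misread as G
        rec = self._one_read_records(bundle, bad, 0)
        at2 = rec[(rec["pos"] == 2) & (rec["strand"] == "+")]
        assert (at2["n_C"] + at2["n_T"]).sum() == 0

    def test_out_of_bounds_hit_raises(self):
        bundle = make_bundle({"chr1": "ACGT" * 30})
        hit = AlignmentHit("r/1", "chr1", 100, "+", 0, 1, oriented_seq=sq.encode("ACGT" * 10))
        with pytest.raises(ValueError):
            pileup_cytosines([hit], bundle)

    def test_mate_overlap_counted_once(self):
        g = "AACGTTCGAA" * 10
        bundle = make_bundle({"chr1": g})
        h1 = AlignmentHit("p/1", "chr1", 0, "+", 0, 1, oriented_seq=sq.encode(g[0:30]))
        h2 = AlignmentHit("p/2", "chr1", 20, "+", 0, 1, oriented_seq=sq.encode(g[20:50]))
        hits = dedupe_mate_overlaps([h1, h2])
        assert hits[1].exclude == (20, 30)
        rec = pileup_cytosines(hits, bundle)
        # every covered plus-strand cytosine seen exactly once
        plus = rec[(rec["strand"] == "+") & (rec["pos"] < 50)]
        assert ((plus["n_C"] + plus["n_T"]) == 1).all()

    def test_emit_all_includes_uncovered_cytosines(self, tiny_bundle):
        rec = pileup_cytosines([], tiny_bundle, emit_all=True)
        assert len(rec) > 0
        assert (rec["n_C"] == 0).all() and (rec["n_T"] == 0).all()


class TestPipelineCounts:
    def test_pileup_matches_generator_bookkeeping(self, tiny_bundle, tiny_params):
        """With error-free reads, alignment+pileup must reproduce exactly
        the counts recomputed from each read's name-encoded true origin."""
        p = tiny_params.with_(coverage=6)
        wt, _ = simulate_methylomes(tiny_bundle, p)
        r1, r2 = simulate_bisulfite_reads(tiny_bundle, wt, p, sample="wt")
        index = build_converted_index(tiny_bundle)
        hits = dedupe_mate_overlaps(align_reads(r1, r2, index, seed=3))
        assert len(hits) == len(r1) + len(r2)  # unique genome: nothing discarded
        rec = pileup_cytosines(hits, tiny_bundle)

        # oracle: place reads by their true origin, counting mate overlaps once
        nC = {c: np.zeros(len(s), dtype=int) for c, s in tiny_bundle.seqs.items()}
        nT = {c: np.zeros(len(s), dtype=int) for c, s in tiny_bundle.seqs.items()}
        for (n1, s1), (n2, s2) in zip(r1, r2):
            chrom, start, fl, strand = n1.split("|")[1:5]
            start, fl, rl = int(start), int(fl), p.read_length
            seen = set()
            for mate, seqstr in ((1, s1), (2, s2)):
                forward = (strand == "+") == (mate == 1)
                rp = sq.encode(seqstr) if forward else sq.revcomp(sq.encode(seqstr))
                off = start if forward else start + fl - rl
                tpl, conv_to = (sq.C, sq.T) if strand == "+" else (sq.G, sq.A)
                for i in np.flatnonzero(tiny_bundle.seqs[chrom][off : off + rl] == tpl):
                    gp = off + int(i)
                    if gp in seen:
                        continue
                    seen.add(gp)
                    if rp[i] == tpl:
                        nC[chrom][gp] += 1
                    elif rp[i] == conv_to:
                        nT[chrom][gp] += 1
        for _, row in rec.iterrows():
            key = (row["chrom"], row["pos"])
            assert nC[row["chrom"]][row["pos"]] == row["n_C"]
            assert nT[row["chrom"]][row["pos"]] == row["n_T"]

    def test_strand_symmetry_under_reverse_complement(self, tiny_bundle, tiny_params):
        """Reverse-complementing genome and reads swaps strands but leaves
        context-resolved methylation fractions unchanged."""
        p = tiny_params.with_(coverage=4)
        wt, _ = simulate_methylomes(tiny_bundle, p)
        r1, r2 = simulate_bisulfite_reads(tiny_bundle, wt, p, sample="wt")
        index = build_converted_index(tiny_bundle)
        rec = pileup_cytosines(
            dedupe_mate_overlaps(align_reads(r1, r2, index, seed=3)), tiny_bundle
        )

        rc_bundle = make_bundle({c: sq.decode(sq.revcomp(s)) for c, s in tiny_bundle.seqs.items()})
        rc_index = build_converted_index(rc_bundle)
        flip = lambda reads: [(n, sq.decode(sq.revcomp(sq.encode(s)))) for n, s in reads]
        # reverse-complementing every read swaps the mate roles
        rc_rec = pileup_cytosines(
            dedupe_mate_overlaps(align_reads(flip(r2), flip(r1), rc_index, seed=3)), rc_bundle
        )
        L = {c: len(s) for c, s in tiny_bundle.seqs.items()}
        rc_rec = rc_rec.assign(
            pos=[L[c] - 1 - p_ for c, p_ in zip(rc_rec["chrom"], rc_rec["pos"])],
            strand=np.where(rc_rec["strand"] == "+", "-", "+"),
        ).sort_values(["chrom", "pos", "strand"], ignore_index=True)
        a = rec.set_index(["chrom", "pos", "strand"]).sort_index()
        b = rc_rec.set_index(["chrom", "pos", "strand"]).sort_index()
        pd.testing.assert_frame_equal(a[["n_C", "n_T"]], b[["n_C", "n_T"]])
        assert (a["context"].values == b["context"].values).all()
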