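"""Generator unit tests: determinism, conservation laws, and recovery of
the configured methylome structure from the emitted ground truth."""

import numpy as np
import pandas as pd
import pytest

import mossmeth._sequtils as sq
from mossmeth.genome import EU_TE, HET_TE
from mossmeth.simulate import (
    PackingError,
    SimParams,
    simulate_bisulfite_reads,
    simulate_expression_counts,
    simulate_genome,
    simulate_methylomes,
)


class TestSimulateGenome:
    def test_zero_te_density_gives_no_tes(self):
        p = SimParams(seed=1, n_chromosomes=1, chrom_length=20_000, te_density=0.0,
                      n_upregulated_te=0)
        b = simulate_genome(p)
        assert len(b.tes) == 0

    def test_total_length_conserved(self):
        p = SimParams(seed=1, n_chromosomes=2, chrom_length=100_000)
        b = simulate_genome(p)
        assert b.total_length == 200_000
        assert all(len(s) == 100_000 for s in b.seqs.values())

    def test_deterministic_given_seed(self, tmp_path):
        from mossmeth.simulate import write_bundle

        p = SimParams(seed=1, n_chromosomes=1, chrom_length=30_000)
        b1 = simulate_genome(p)
        b2 = simulate_genome(p)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(b1, d1)
        write_bundle(b2, d2)
        for name in ("genome.fa", "tes.bed", "genes.bed"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_annotations_non_overlapping(self, tiny_bundle):
        feats = pd.concat(
            [tiny_bundle.tes[["chrom", "start", "end"]], tiny_bundle.genes[["chrom", "start", "end"]]]
        ).sort_values(["chrom", "start"])
        for _, sub in feats.groupby("chrom"):
            assert (sub["start"].values[1:] >= sub["end"].values[:-1]).all()

    def test_ltr_tes_have_terminal_sub_intervals(self, tiny_bundle):
        ltr = tiny_bundle.tes[tiny_bundle.tes["te_class"] == "LTR"]
        assert len(ltr) > 0
        assert (ltr["ltr5_start"] == ltr["start"]).all()
        assert (ltr["ltr3_end"] == ltr["end"]).all()
        assert (ltr["ltr5_end"] < ltr["ltr3_start"]).all()  # internal region exists

    def test_heterochromatic_compartment_has_higher_gc_and_marks(self, tiny_bundle):
        tr = tiny_bundle.tracks
        comp = tiny_bundle.compartment_arrays
        mid = (tr["start"] + tr["end"]) // 2
        codes = np.array([comp[c][m] for c, m in zip(tr["chrom"], mid)])
        het, eu = codes == HET_TE, codes == EU_TE
        assert tr.loc[het, "gc"].mean() > tr.loc[eu, "gc"].mean() + 0.1
        assert tr.loc[het, "h3"].mean() > tr.loc[eu, "h3"].mean() + 0.2
        assert tr.loc[het, "h3k9me2"].mean() > tr.loc[eu, "h3k9me2"].mean() + 0.3

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            simulate_genome(SimParams(te_density=0.95, gene_density=0.5))


class TestSimulateMethylomes:
    def test_identity_when_no_reduction(self, tiny_bundle):
        p = SimParams(seed=7, mutant_reduction=(0, 0, 0), chh_hyper_gain=0.0,
                      n_upregulated_te=0)
        wt, mut = simulate_methylomes(tiny_bundle, p)
        for c in tiny_bundle.chroms:
            np.testing.assert_array_equal(wt.p_plus[c], mut.p_plus[c])
            np.testing.assert_array_equal(wt.p_minus[c], mut.p_minus[c])

    def test_reduction_arithmetic_is_multiplicative(self, tiny_bundle):
        p = SimParams(seed=7, mutant_reduction=(0.75, 0.5, 0.0), chh_hyper_gain=0.0,
                      n_upregulated_te=0)
        wt, mut = simulate_methylomes(tiny_bundle, p)
        wt_df, mut_df = wt.to_frame(), mut.to_frame()
        ratio = mut_df["p_meth"] / wt_df["p_meth"].where(wt_df["p_meth"] > 0)
        cg = wt_df["context"] == "CG"
        np.testing.assert_allclose(ratio[cg].dropna(), 0.25, atol=1e-12)
        chg = wt_df["context"] == "CHG"
        np.testing.assert_allclose(ratio[chg].dropna(), 0.5, atol=1e-12)

    def test_ground_truth_covers_every_cytosine_exactly_once(self, tiny_bundle, tiny_truths):
        wt, _ = tiny_truths
        n_cg_bases = sum(
            int(((s == sq.C) | (s == sq.G)).sum()) for s in tiny_bundle.seqs.values()
        )
        assert wt.n_records() == n_cg_bases
        for c, s in tiny_bundle.seqs.items():
            assert not np.isfinite(wt.p_plus[c][s != sq.C]).any()
            assert not np.isfinite(wt.p_minus[c][s != sq.G]).any()

    def test_probabilities_in_unit_interval(self, tiny_truths):
        for t in tiny_truths:
            for arr in list(t.p_plus.values()) + list(t.p_minus.values()):
                vals = arr[np.isfinite(arr)]
                assert vals.min() >= 0 and vals.max() <= 1

    def test_chh_redistribution_signs_from_bookkeeping(self, tiny_bundle):
        """Hyper-gain raises euchromatic low-CHH positions; the 24.1%-style
        reduction lowers heterochromatic CHH — recomputed from the emitted
        ground-truth table itself."""
        p = SimParams(seed=7, chh_hyper_gain=0.1, n_upregulated_te=0)
        wt, mut = simulate_methylomes(tiny_bundle, p)
        wt_df, mut_df = wt.to_frame(), mut.to_frame()
        chh = wt_df["context"] == "CHH"
        diff = mut_df["p_meth"] - wt_df["p_meth"]
        eu = chh & (wt_df["compartment"] == "euchromatic_te")
        het = chh & (wt_df["compartment"] == "heterochromatic_te")
        assert diff[eu].mean() > 0
        assert diff[het].mean() < 0

    def test_increasing_cg_reduction_strictly_lowers_te_cg(self, tiny_bundle):
        means = []
        for r in (0.2, 0.5, 0.8):
            p = SimParams(seed=7, mutant_reduction=(r, 0.5, 0.2), n_upregulated_te=0)
            _, mut = simulate_methylomes(tiny_bundle, p)
            df = mut.to_frame()
            te = df["compartment"].isin(["euchromatic_te", "heterochromatic_te"])
            means.append(df.loc[te & (df["context"] == "CG"), "p_meth"].mean())
        assert means[0] > means[1] > means[2]

    def test_predisposed_tes_are_ltr_depleted(self, tiny_bundle, tiny_params, tiny_truths):
        wt, _ = tiny_truths
        pre = tiny_bundle.tes[tiny_bundle.tes["predisposed"] & tiny_bundle.tes["ltr5_start"].notna()]
        assert len(pre) > 0
        for _, te in pre.iterrows():
            arr = wt.p_plus[te["chrom"]]
            ltr = np.nanmean(arr[int(te["ltr5_start"]) : int(te["ltr5_end"])])
            inner = np.nanmean(arr[int(te["ltr5_end"]) : int(te["ltr3_start"])])
            assert ltr < inner


class TestSimulateReads:
    def test_read_pair_count_formula(self, tiny_bundle, tiny_truths, tiny_params):
        wt, _ = tiny_truths
        p = tiny_params.with_(coverage=30)
        r1, r2 = simulate_bisulfite_reads(tiny_bundle, wt, p, sample="x")
        expected = round(30 * tiny_bundle.total_length / (2 * p.read_length))
        assert len(r1) == len(r2) == expected

    def test_complete_conversion_leaves_no_templated_c(self, tiny_bundle, tiny_params):
        p = tiny_params.with_(wt_levels=(0, 0, 0), gene_cg_level=0, background_level=0,
                              wt_chh_euchromatic=0, coverage=3)
        wt, _ = simulate_methylomes(tiny_bundle, p)
        r1, r2 = simulate_bisulfite_reads(tiny_bundle, wt, p, sample="x")
        for name, seqstr in r1 + r2:
            chrom, start, fl, strand = name.split("|")[1:5]
            frag = tiny_bundle.seqs[chrom][int(start) : int(start) + int(fl)]
            mate = name[-1]
            forward = (strand == "+") == (mate == "1")
            read_plus = sq.encode(seqstr) if forward else sq.revcomp(sq.encode(seqstr))
            gslice = frag[: p.read_length] if forward else frag[-p.read_length :]
            templated = sq.C if strand == "+" else sq.G
            converted = sq.T if strand == "+" else sq.A
            np.testing.assert_array_equal(read_plus[gslice == templated], converted)

    def test_full_protection_keeps_every_templated_c(self, tiny_bundle, tiny_params):
        p = tiny_params.with_(wt_levels=(1, 1, 1), gene_cg_level=1, background_level=1,
                              wt_chh_euchromatic=1, predisposed_ltr_scale=1.0, coverage=3)
        wt, _ = simulate_methylomes(tiny_bundle, p)
        r1, r2 = simulate_bisulfite_reads(tiny_bundle, wt, p, sample="x")
        for name, seqstr in r1 + r2:
            chrom, start, fl, strand = name.split("|")[1:5]
            frag = tiny_bundle.seqs[chrom][int(start) : int(start) + int(fl)]
            mate = name[-1]
            forward = (strand == "+") == (mate == "1")
            read_plus = sq.encode(seqstr) if forward else sq.revcomp(sq.encode(seqstr))
            gslice = frag[: p.read_length] if forward else frag[-p.read_length :]
            templated = sq.C if strand == "+" else sq.G
            np.testing.assert_array_equal(read_plus[gslice == templated], templated)

    def test_read_length_exceeding_chromosome_raises(self, tiny_bundle, tiny_truths, tiny_params):
        wt, _ = tiny_truths
        with pytest.raises(ValueError, match="read_length"):
            simulate_bisulfite_reads(tiny_bundle, wt, tiny_params.with_(read_length=50_000))

    def test_deterministic_reads(self, tiny_bundle, tiny_truths, tiny_params):
        wt, _ = tiny_truths
        a = simulate_bisulfite_reads(tiny_bundle, wt, tiny_params, sample="wt")
        b = simulate_bisulfite_reads(tiny_bundle, wt, tiny_params, sample="wt")
        assert a == b
        c = simulate_bisulfite_reads(tiny_bundle, wt, tiny_params, sample="mut")
        assert c != a  # different sample label, different library


class TestSimulateExpression:
    def test_no_fold_change_gives_empty_truth(self, tiny_bundle, tiny_params):
        _, truth = simulate_expression_counts(tiny_bundle, tiny_params.with_(de_fold=1.0))
        assert truth.empty

    def test_deterministic_counts(self, tiny_bundle, tiny_params):
        m1, _ = simulate_expression_counts(tiny_bundle, tiny_params)
        m2, _ = simulate_expression_counts(tiny_bundle, tiny_params)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_nb_mean_matches_specification(self, tiny_bundle, tiny_params):
        """Law of large numbers: per-feature mean over 200 replicates is
        within 5% of the configured NB mean (checked on high-mean genes)."""
        p = tiny_params.with_(n_reps=200, de_fold=1.0)
        matrix, _ = simulate_expression_counts(tiny_bundle, p)
        rng = np.random.default_rng([7, 4, 0])  # the generator's own stream
        n = len(matrix.meta)
        base = np.where(
            matrix.meta["kind"] == "gene",
            rng.lognormal(np.log(150), 1.0, n),
            rng.lognormal(np.log(4.0), 1.0, n),
        )
        base = np.where(matrix.meta["predisposed"], p.predisposed_base_mean, base)
        wt_mean = matrix.counts[matrix.columns_for("wt")].mean(axis=1).values
        big = base > 30
        assert big.sum() >= 5
        np.testing.assert_allclose(wt_mean[big], base[big], rtol=0.05)

    def test_truth_table_matches_predisposed_flags(self, tiny_bundle, tiny_params):
        matrix, truth = simulate_expression_counts(tiny_bundle, tiny_params)
        flagged = set(matrix.meta.index[matrix.meta["predisposed"]])
        assert set(truth["feature"]) == flagged
        assert len(flagged) == tiny_params.n_upregulated_te
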