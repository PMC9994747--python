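"""End-to-end orchestration: simulate -> align -> call -> compare -> profile
-> expression, with a machine-readable run report.

The pipeline is deterministic: every random stage derives its generator
from the configured seed, and the report records SHA-256 hashes of all
written files so two runs with one seed can be compared bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from . import io as mio
from .align import align_reads, build_converted_index, dedupe_mate_overlaps, pileup_cytosines
from .calling import te_methylation_table, window_methylation
from .diffmeth import (
    chromosome_profile,
    estimate_context_reduction,
    percent_change_table,
    select_matched_windows,
    stratify_by_attribute,
)
from .expression import differential_expression, family_rpm
from .genome import GenomeBundle
from .metaprofile import te_metaprofile
from .simulate import (
    SimParams,
    simulate_bisulfite_reads,
    simulate_expression_counts,
    simulate_genome,
    simulate_methylomes,
    write_bundle,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration; every field has a default and the
    config round-trips through ``to_dict``/``from_dict`` unchanged."""

    sim: SimParams = field(default_factory=SimParams)
    seed: int = 0
    outdir: str | None = None
    # stage toggles
    do_align: bool = True
    do_methylation: bool = True
    do_diffmeth: bool = True
    do_metaprofile: bool = True
    do_expression: bool = True
    # stage parameters
    width: int = 50
    step: int | None = None
    min_calls: int = 4
    max_mismatches: int = 2
    max_hits: int = 10
    min_meth: float = 0.5
    n_quantiles: int = 5
    chrom_window: int = 100_000
    meta_anchor: str = "5prime"
    meta_bin: int = 100
    meta_max_offset: int = 2000
    min_count: int = 10
    fc: float = 2.0
    alpha: float = 0.05

    def __post_init__(self):
        # keep the simulation seed slaved to the run seed unless it was
        # set explicitly different from the default
        if self.sim.seed == 0 and self.seed != 0:
            self.sim = self.sim.with_(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            if "wt_levels" in sim:
                sim["wt_levels"] = tuple(sim["wt_levels"])
            if "mutant_reduction" in sim:
                sim["mutant_reduction"] = tuple(sim["mutant_reduction"])
            sim = SimParams(**sim)
        return cls(sim=sim, **d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | None = None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run report: per-context TE methylation reductions,
    matched-window medians, CHH quantile stratification, DE counts, the
    upregulated-TE methylation contrast, a file manifest with SHA-256
    hashes, versions and the seed. Disabled stages are skipped and their
    report fields omitted; a stage whose inputs were disabled raises a
    clear error naming the missing stage.
    """
    outdir = outdir or config.outdir
    out = mio.ensure_dir(outdir) if outdir else None
    sim = config.sim
    report: dict = {
        "seed": config.seed,
        "versions": {"mossmeth": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "params": config.to_dict(),
    }
    manifest: dict[str, str] = {}

    logger.info("simulating genome (%d x %d bp)", sim.n_chromosomes, sim.chrom_length)
    bundle = simulate_genome(sim)
    truth_wt, truth_mut = simulate_methylomes(bundle, sim)
    report["n_tes"] = int(len(bundle.tes))
    report["n_genes"] = int(len(bundle.genes))
    if out:
        for name, p in write_bundle(bundle, out / "genome").items():
            manifest[f"genome/{p.name}"] = _sha256(p)

    windows = {}
    records = {}
    if config.do_align or config.do_methylation or config.do_diffmeth or config.do_metaprofile:
        if not config.do_align:
            raise RuntimeError("methylation stages require the align stage")
        index = build_converted_index(bundle)
        for sample, truth in (("wt", truth_wt), ("mut", truth_mut)):
            logger.info("simulating and aligning %s bisulfite reads", sample)
            r1, r2 = simulate_bisulfite_reads(bundle, truth, sim, sample=sample)
            hits = align_reads(r1, r2, index, max_mismatches=config.max_mismatches,
                               max_hits=config.max_hits, seed=config.seed)
            hits = dedupe_mate_overlaps(hits)
            rec = pileup_cytosines(hits, bundle)
            records[sample] = rec
            report[f"n_read_pairs_{sample}"] = len(r1)
            report[f"n_aligned_reads_{sample}"] = len(hits)

    if config.do_methylation:
        for sample, rec in records.items():
            windows[sample] = window_methylation(
                rec, bundle, width=config.width, step=config.step, min_calls=config.min_calls
            )
        te_meth = te_methylation_table(records, bundle)
        if out:
            p = out / "te_methylation.tsv"
            mio.write_tsv(p, te_meth)
            manifest[p.name] = _sha256(p)
            for sample, win in windows.items():
                p = out / f"windows_{sample}.tsv"
                mio.write_tsv(p, win)
                manifest[p.name] = _sha256(p)

    if config.do_diffmeth:
        if not config.do_methylation:
            raise RuntimeError("diffmeth stage requires the methylation stage")
        red = estimate_context_reduction(windows["wt"], windows["mut"], bundle)
        report["pct_reduction"] = {
            r["context"]: r["pct_reduction"] for _, r in red.iterrows()
        }
        report["te_methylation"] = {
            r["context"]: {"wt": r["m_wt"], "mut": r["m_mut"]} for _, r in red.iterrows()
        }
        matched, msummary = select_matched_windows(
            windows["wt"], windows["mut"], min_meth=config.min_meth
        )
        report["matched_windows"] = {
            "n": int(len(matched)),
            "median_diff_wt": float(msummary.loc[0, "median"]),
            "median_diff_mut": float(msummary.loc[1, "median"]),
        }
        chh = percent_change_table(windows["wt"], windows["mut"], context="CHH",
                                   te_only=True, genome=bundle)
        strat = None
        if len(chh) >= config.n_quantiles:
            strat = stratify_by_attribute(chh, chh["m_a"].values, config.n_quantiles)
            report["chh_stratification"] = {
                "attribute": "wt_mCHH",
                "median_lowest_quantile": float(strat.iloc[0]["median"]),
                "median_highest_quantile": float(strat.iloc[-1]["median"]),
            }
        profiles = {s: chromosome_profile(records[s], bundle, window=config.chrom_window)
                    for s in records}
        if out:
            tables = {"matched_windows.tsv": matched, "chh_percent_change.tsv": chh}
            if strat is not None:
                tables["chh_stratification.tsv"] = strat
            for s, prof in profiles.items():
                tables[f"chrom_profile_{s}.tsv"] = prof
            for name, df in tables.items():
                p = out / name
                mio.write_tsv(p, df)
                manifest[p.name] = _sha256(p)

    if config.do_metaprofile:
        if not records:
            raise RuntimeError("metaprofile stage requires the align stage")
        meta = te_metaprofile(records, bundle, anchor=config.meta_anchor,
                              bin=config.meta_bin, max_offset=config.meta_max_offset)
        if out:
            p = out / "metaprofile.tsv"
            mio.write_tsv(p, meta)
            manifest[p.name] = _sha256(p)

    if config.do_expression:
        matrix, truth_de = simulate_expression_counts(bundle, sim)
        de = differential_expression(matrix, min_count=config.min_count,
                                     fc=config.fc, alpha=config.alpha)
        te_de = de[de["kind"] == "te"]
        report["de"] = {
            "n_up_te": int((te_de["status"] == "up").sum()),
            "n_down_te": int((te_de["status"] == "down").sum()),
            "n_up_gene": int((de[(de["kind"] == "gene") & (de["status"] == "up")]).shape[0]),
            "n_true_up": int(len(truth_de)),
        }
        rpm = family_rpm(matrix)
        if config.do_methylation:
            te_meth_cmp = te_methylation_table(records, bundle)
            contrast = upregulated_te_methylation_contrast(de, te_meth_cmp)
            report["upregulated_contrast"] = contrast
        if out:
            p = out / "de_results.tsv"
            mio.write_tsv(p, de)
            manifest[p.name] = _sha256(p)
            p = out / "family_rpm.tsv"
            mio.write_tsv(p, rpm)
            manifest[p.name] = _sha256(p)

    report["manifest"] = manifest
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def upregulated_te_methylation_contrast(de: pd.DataFrame, te_meth: pd.DataFrame) -> dict:
    """Compare WT methylation of upregulated vs unaffected TEs.

    ``te_meth`` is the per-TE table with whole/internal/LTR WT and mutant
    fractions (from :func:`calling.te_methylation_table`); DE status joins
    on the TE name. Reports group medians for whole/internal/LTR WT
    methylation and the whole-element percent change, plus a rank-based
    (Mann-Whitney) effect size on WT LTR methylation: negative values mean
    the upregulated group is the more LTR-hypomethylated one.
    """
    te_de = de[de["kind"] == "te"][["feature", "status"]]
    merged = te_meth.merge(te_de, left_on="name", right_on="feature", how="inner")
    merged = merged[merged["status"].isin(["up", "unchanged", "down"])]
    merged["group"] = np.where(merged["status"] == "up", "upregulated", "unaffected")

    from .diffmeth import percent_change

    ok = merged["m_whole_wt"].notna() & merged["m_whole_mut"].notna()
    merged["pct_change_whole"] = np.nan
    merged.loc[ok, "pct_change_whole"] = percent_change(
        merged.loc[ok, "m_whole_wt"].values, merged.loc[ok, "m_whole_mut"].values
    )

    out: dict = {"n_upregulated": int((merged["group"] == "upregulated").sum()),
                 "n_unaffected": int((merged["group"] == "unaffected").sum())}
    if out["n_upregulated"] == 0:
        logger.warning("no upregulated TEs; contrast summarises unaffected only")
    for metric in ("m_whole_wt", "m_internal_wt", "m_ltr_wt", "pct_change_whole"):
        for group in ("upregulated", "unaffected"):
            vals = merged.loc[merged["group"] == group, metric].dropna()
            out[f"median_{metric}_{group}"] = float(vals.median()) if len(vals) else float("nan")

    up = merged.loc[merged["group"] == "upregulated", "m_ltr_wt"].dropna()
    un = merged.loc[merged["group"] == "unaffected", "m_ltr_wt"].dropna()
    if len(up) and len(un):
        u_stat = stats.mannwhitneyu(up, un, alternative="two-sided").statistic
        out["ltr_effect_size"] = float(2.0 * u_stat / (len(up) * len(un)) - 1.0)
        out["ltr_mannwhitney_p"] = float(
            stats.mannwhitneyu(up, un, alternative="two-sided").pvalue
        )
    return out
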