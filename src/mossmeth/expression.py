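"""Read counting over genes/TEs, family-level RPM, and differential
expression with simple fixed thresholds.

Differential calls use a pooled-variance two-sample t-test on
log2(CPM + 0.5) — at three replicates per genotype the pooled test holds
its nominal size, where the unequal-variance (Welch) variant is markedly
conservative — with the decisive filters applied exactly: features with a
summed read count below ``min_count`` are omitted, and a feature is called
up (down) when its fold-change is at least ``fc`` and p < ``alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Feature x replicate read counts with genotype labels.

    ``counts`` is indexed by feature id with one column per replicate;
    ``meta`` carries feature kind (gene/te) and TE family; ``genotypes``
    maps column name to genotype label. Library sizes are the column sums
    of assigned reads.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    genotypes: dict[str, str]

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def columns_for(self, genotype: str) -> list[str]:
        return [c for c, g in self.genotypes.items() if g == genotype]


def read_count_matrix(path) -> CountMatrix:
    """Load a count TSV: feature, kind, family columns plus one column per
    replicate named ``<genotype>_<n>`` (e.g. wt_1 ... mut_3)."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in ("feature", "kind", "family", "predisposed") if c in df.columns]
    rep_cols = [c for c in df.columns if c not in meta_cols]
    meta = df[meta_cols].set_index("feature")
    if "predisposed" not in meta:
        meta["predisposed"] = False
    counts = df.set_index("feature")[rep_cols].astype(np.int64)
    genotypes = {c: c.rsplit("_", 1)[0] for c in rep_cols}
    return CountMatrix(counts=counts, meta=meta, genotypes=genotypes)


def write_count_matrix(path, matrix: CountMatrix) -> None:
    out = matrix.meta.reset_index().merge(
        matrix.counts.reset_index(), on="feature", how="right"
    )
    out.to_csv(path, sep="\t", index=False)


def count_features(
    placements: pd.DataFrame,
    annotations: pd.DataFrame,
    max_hits: int = 100,
    seed: int = 0,
    sample: str = "sample",
) -> pd.Series:
    """Assign reads to features and total them.

    ``placements`` has one row per candidate placement with columns
    read_id, chrom, start, end; a read's candidate count decides its fate:
    1 → assigned there; 2..max_hits-1 → one placement chosen by a seeded
    uniform draw; >= max_hits → discarded. A placed read is assigned to the
    feature covering >= 50% of it; if two features qualify the larger
    overlap wins, with ties going to the TE.

    ``annotations`` needs columns chrom, start, end, name, kind
    ('gene'/'te'). Returns per-feature read totals (all features present,
    zero-filled).
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 11])
    counts = pd.Series(0, index=annotations["name"], dtype=np.int64)

    ann_by_chrom = {c: sub.reset_index(drop=True) for c, sub in annotations.groupby("chrom")}

    chosen = []
    for read_id, group in placements.groupby("read_id", sort=True):
        n = len(group)
        if n >= max_hits:
            continue
        row = group.iloc[0] if n == 1 else group.iloc[int(rng.integers(n))]
        chosen.append(row)
    for row in chosen:
        sub = ann_by_chrom.get(row["chrom"])
        if sub is None:
            continue
        ov = np.minimum(sub["end"], row["end"]) - np.maximum(sub["start"], row["start"])
        rlen = row["end"] - row["start"]
        good = sub[ov >= 0.5 * rlen].copy()
        if good.empty:
            continue
        if len(good) > 1:
            good_ov = ov[good.index]
            best = good_ov.max()
            best_rows = good[good_ov == best]
            if len(best_rows) > 1 and (best_rows["kind"] == "te").any():
                best_rows = best_rows[best_rows["kind"] == "te"]
                logger.debug("ambiguous placement %s resolved to TE", row["read_id"])
            feat = best_rows.iloc[0]["name"]
        else:
            feat = good.iloc[0]["name"]
        counts[feat] += 1
    return counts


def family_rpm(matrix: CountMatrix, families: pd.Series | None = None) -> pd.DataFrame:
    """Per-family mean RPM and standard error per genotype.

    Family counts sum member TE counts per replicate; RPM normalises by
    that replicate's library size. With a single replicate the SE is
    emitted as missing.
    """
    lib = matrix.lib_sizes
    if (lib == 0).any():
        raise ValueError("zero library size")
    fam = families if families is not None else matrix.meta["family"]
    te_mask = (matrix.meta["kind"] == "te") & (fam != "")
    sub = matrix.counts[te_mask]
    fam_counts = sub.groupby(fam[te_mask]).sum()
    rpm = fam_counts.div(lib, axis=1) * 1e6

    rows = []
    for family in rpm.index:
        for genotype in sorted(set(matrix.genotypes.values())):
            cols = matrix.columns_for(genotype)
            vals = rpm.loc[family, cols].astype(float)
            rows.append(
                {
                    "family": family,
                    "genotype": genotype,
                    "mean_rpm": vals.mean(),
                    "se_rpm": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
                    "n_reps": len(vals),
                }
            )
    return pd.DataFrame(rows)


def differential_expression(
    matrix: CountMatrix,
    min_count: int = 10,
    fc: float = 2.0,
    alpha: float = 0.05,
    group_a: str = "wt",
    group_b: str = "mut",
) -> pd.DataFrame:
    """Threshold-based differential expression between two genotypes.

    Features whose summed count (all replicates) is below ``min_count``
    get status ``filtered``. Remaining features are normalised to CPM,
    log2(CPM + 0.5) transformed, and compared with a two-sided pooled
    t-test. Status is ``up`` when log2FC >= log2(fc) and p < alpha,
    ``down`` symmetrically, else ``unchanged``. Zero variance in both
    groups yields p = 1 for equal means and p = 0 otherwise.
    """
    cols_a = matrix.columns_for(group_a)
    cols_b = matrix.columns_for(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per genotype")

    counts = matrix.counts
    total = counts.sum(axis=1)
    cpm = counts.div(matrix.lib_sizes, axis=1) * 1e6
    logcpm = np.log2(cpm + 0.5)

    a = logcpm[cols_a].values
    b = logcpm[cols_b].values
    log2fc = b.mean(axis=1) - a.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=True)
    pval = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    pval[zero_var & (log2fc == 0)] = 1.0
    pval[zero_var & (log2fc != 0)] = 0.0

    out = pd.DataFrame(
        {"feature": counts.index, "log2fc": log2fc, "pvalue": pval, "total_count": total.values}
    )
    thr = np.log2(fc)
    status = np.full(len(out), "unchanged", dtype=object)
    status[(out["log2fc"] >= thr) & (out["pvalue"] < alpha)] = "up"
    status[(out["log2fc"] <= -thr) & (out["pvalue"] < alpha)] = "down"
    status[total.values < min_count] = "filtered"
    out["status"] = status
    out = out.merge(matrix.meta.reset_index(), on="feature", how="left")
    return out
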