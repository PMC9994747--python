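import numpy as np
import pandas as pd
import pytest

from mossmeth.align import (
    align_reads,
    build_converted_index,
    dedupe_mate_overlaps,
    pileup_cytosines,
)
from mossmeth.genome import GenomeBundle
from mossmeth.simulate import (
    SimParams,
    simulate_bisulfite_reads,
    simulate_genome,
    simulate_methylomes,
)

TE_COLUMNS = [
    "chrom", "start", "end", "strand", "family", "te_class", "compartment",
    "name", "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end", "predisposed",
]


def make_bundle(seqs: dict[str, str], tes=None, genes=None) -> GenomeBundle:
    """Hand-built bundle: tes/genes as lists of dicts with sensible defaults."""
    import mossmeth._sequtils as sq

    te_rows = []
    for i, t in enumerate(tes or []):
        row = {
            "strand": "+", "family": "Gypsy1", "te_class": "DNA",
            "compartment": "heterochromatic", "name": f"TE{i + 1:05d}",
            "ltr5_start": np.nan, "ltr5_end": np.nan,
            "ltr3_start": np.nan, "ltr3_end": np.nan, "predisposed": False,
        }
        row.update(t)
        te_rows.append(row)
    gene_rows = []
    for i, g in enumerate(genes or []):
        row = {"strand": "+", "name": f"G{i + 1:05d}"}
        row.update(g)
        gene_rows.append(row)
    return GenomeBundle(
        seqs={c: sq.encode(s) for c, s in seqs.items()},
        tes=pd.DataFrame(te_rows, columns=TE_COLUMNS),
        genes=pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "name"]),
    )


def records_frame(rows):
    """Cytosine record table from (chrom, pos, strand, context, n_C, n_T) rows."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "n_C", "n_T"])


@pytest.fixture(scope="session")
def tiny_params():
    return SimParams(seed=7, n_chromosomes=1, chrom_length=40_000, coverage=10,
                     n_upregulated_te=4)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_params):
    return simulate_genome(tiny_params)


@pytest.fixture(scope="session")
def tiny_truths(tiny_bundle, tiny_params):
    return simulate_methylomes(tiny_bundle, tiny_params)


@pytest.fixture(scope="session")
def tiny_index(tiny_bundle):
    return build_converted_index(tiny_bundle)


@pytest.fixture(scope="session")
def tiny_records(tiny_bundle, tiny_truths, tiny_params, tiny_index):
    """Aligned, piled-up cytosine records for the tiny WT sample."""
    wt, _ = tiny_truths
    r1, r2 = simulate_bisulfite_reads(tiny_bundle, wt, tiny_params, sample="wt")
    hits = dedupe_mate_overlaps(align_reads(r1, r2, tiny_index, seed=7))
    return pileup_cytosines(hits, tiny_bundle)
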