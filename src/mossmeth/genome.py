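"""The in-memory genome container shared by every pipeline stage.

A :class:`GenomeBundle` carries chromosome sequences (uint8 ASCII arrays),
gene and TE annotations (pandas DataFrames, 0-based half-open), per-50-bp
chromatin tracks, and derived per-position label arrays used for fast
interval arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from . import _sequtils as sq

# compartment codes for per-position label arrays
INTERGENIC, GENE, EU_TE, HET_TE = 0, 1, 2, 3
COMPARTMENT_NAMES = {
    INTERGENIC: "intergenic",
    GENE: "gene",
    EU_TE: "euchromatic_te",
    HET_TE: "heterochromatic_te",
}

TRACK_BIN = 50  # bp per chromatin-track step


@dataclass
class GenomeBundle:
    """Sequences plus annotations plus chromatin tracks.

    Attributes
    ----------
    seqs:
        ``{chrom: uint8 array}`` of ASCII base codes.
    genes:
        DataFrame with columns chrom, start, end, strand, name.
    tes:
        DataFrame with columns chrom, start, end, strand, name, family,
        te_class, compartment, predisposed and, for LTR-class elements,
        ltr5_start/ltr5_end/ltr3_start/ltr3_end (NaN otherwise).
    tracks:
        DataFrame with columns chrom, start, end, gc, h3, h3k9me2 on a
        fixed 50-bp step.
    """

    seqs: dict[str, np.ndarray]
    genes: pd.DataFrame
    tes: pd.DataFrame
    tracks: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def chroms(self) -> list[str]:
        return list(self.seqs)

    def chrom_length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    @cached_property
    def te_id_arrays(self) -> dict[str, np.ndarray]:
        """Per-position TE row index (-1 outside TEs), per chromosome."""
        out = {c: np.full(len(s), -1, dtype=np.int32) for c, s in self.seqs.items()}
        for idx, row in self.tes.iterrows():
            out[row["chrom"]][int(row["start"]) : int(row["end"])] = idx
        return out

    @cached_property
    def gene_id_arrays(self) -> dict[str, np.ndarray]:
        out = {c: np.full(len(s), -1, dtype=np.int32) for c, s in self.seqs.items()}
        for idx, row in self.genes.iterrows():
            out[row["chrom"]][int(row["start"]) : int(row["end"])] = idx
        return out

    @cached_property
    def compartment_arrays(self) -> dict[str, np.ndarray]:
        """Per-position compartment code, per chromosome."""
        out = {c: np.full(len(s), INTERGENIC, dtype=np.int8) for c, s in self.seqs.items()}
        for _, row in self.genes.iterrows():
            out[row["chrom"]][int(row["start"]) : int(row["end"])] = GENE
        for _, row in self.tes.iterrows():
            code = HET_TE if row["compartment"] == "heterochromatic" else EU_TE
            out[row["chrom"]][int(row["start"]) : int(row["end"])] = code
        return out

    @cached_property
    def annotated_arrays(self) -> dict[str, np.ndarray]:
        """Boolean per-position mask of any annotated feature (gene or TE)."""
        return {
            c: (self.te_id_arrays[c] >= 0) | (self.gene_id_arrays[c] >= 0)
            for c in self.seqs
        }

    def ltr_mask_arrays(self) -> dict[str, np.ndarray]:
        """Per-position mask of LTR sub-intervals of LTR-class TEs."""
        out = {c: np.zeros(len(s), dtype=bool) for c, s in self.seqs.items()}
        ltr = self.tes[self.tes["te_class"] == "LTR"]
        for _, row in ltr.iterrows():
            arr = out[row["chrom"]]
            arr[int(row["ltr5_start"]) : int(row["ltr5_end"])] = True
            arr[int(row["ltr3_start"]) : int(row["ltr3_end"])] = True
        return out

    def subsequence(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.seqs[chrom][start:end]

    def as_strings(self) -> dict[str, str]:
        return {c: sq.decode(s) for c, s in self.seqs.items()}
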