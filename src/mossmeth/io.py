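"""Readers and writers for the standard genomics text formats the pipeline
exchanges: FASTA, BED6+, GFF3, BedGraph, FASTQ (optionally gzipped) and
tab-separated tables.

Coordinates are 0-based half-open everywhere in memory; GFF3 output is
converted to 1-based closed on the way out, and the CX-style cytosine table
is written with 1-based positions to match the convention of existing
methylation extractors.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import _sequtils as sq


def write_fasta(path, seqs: dict[str, np.ndarray], width: int = 70) -> None:
    """Write ``{name: uint8 array}`` sequences to a FASTA file."""
    with open(path, "w") as fh:
        for name, arr in seqs.items():
            fh.write(f">{name}\n")
            s = sq.decode(arr)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path) -> dict[str, np.ndarray]:
    return {rec.id: sq.encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(path, df: pd.DataFrame, name_cols: Sequence[str] = ("name",)) -> None:
    """Write intervals as BED6+; name field joins ``name_cols`` with ':'."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": df[list(name_cols)].astype(str).agg(":".join, axis=1),
            "score": 0,
            "strand": df.get("strand", "."),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_gff3(path, df: pd.DataFrame, source: str, feature_type: str) -> None:
    """Write intervals as GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in df.iterrows():
            attrs = f"ID={row['name']}"
            if "family" in row.index and pd.notna(row.get("family")):
                attrs += f";family={row['family']}"
            fh.write(
                f"{row['chrom']}\t{source}\t{feature_type}\t{int(row['start']) + 1}\t"
                f"{int(row['end'])}\t.\t{row.get('strand', '.')}\t.\t{attrs}\n"
            )


def write_bedgraph(path, df: pd.DataFrame, value_col: str) -> None:
    """Write a (chrom,start,end,value) track; NaN-valued rows are dropped."""
    sub = df.loc[df[value_col].notna(), ["chrom", "start", "end", value_col]].copy()
    sub["start"] = sub["start"].astype(int)
    sub["end"] = sub["end"].astype(int)
    sub.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_fastq(path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write ``(name, sequence)`` pairs as FASTQ; gzipped when path ends .gz."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header[1:], seq))
    return reads


def read_bed(path) -> pd.DataFrame:
    """Read BED6 intervals; the name field's 'family:class' is split out."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    parts = df["name"].astype(str).str.split(":", n=1, expand=True)
    df["family"] = parts[0]
    df["te_class"] = parts[1] if parts.shape[1] > 1 else ""
    return df


def write_cx_table(path, records: pd.DataFrame) -> None:
    """Write per-cytosine calls as a CX-style TSV (1-based positions)."""
    out = records.copy()
    out["pos"] = out["pos"].astype(int) + 1
    cols = ["chrom", "pos", "strand", "n_C", "n_T", "context", "trinucleotide"]
    out[cols].to_csv(path, sep="\t", header=True, index=False)


def read_cx_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"].astype(int) - 1
    return df


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
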