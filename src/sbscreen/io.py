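"""Readers and writers for the plain-text formats the pipeline exchanges.

All intermediate artifacts are tab-separated text (insertions, thresholds,
manifest, refFlat, expression) or JSON (ground truth), so every stage can be
inspected and tested independently.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

INSERTION_COLUMNS = ["sample_id", "library", "chrom", "ta_pos", "orientation", "read_count"]

REFFLAT_COLUMNS = [
    "geneName",
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
]


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_refflat(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as 11-column UCSC refFlat (0-based half-open, comma lists)."""
    out = genes.copy()
    for col in ("exonStarts", "exonEnds"):
        out[col] = out[col].map(lambda xs: ",".join(str(x) for x in xs) + ",")
    out[REFFLAT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_refflat(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", header=None, names=REFFLAT_COLUMNS)
    for col in ("exonStarts", "exonEnds"):
        genes[col] = genes[col].map(
            lambda s: tuple(int(x) for x in str(s).rstrip(",").split(","))
        )
    return genes


def write_insertions(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_insertions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed6(table: pd.DataFrame, path: str | Path) -> None:
    """Export insertion calls as BED6: the TA dinucleotide as a 2-bp interval."""
    bed = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "start": table["ta_pos"],
            "end": table["ta_pos"] + 2,
            "name": table["sample_id"],
            "score": table["read_count"],
            "strand": table["orientation"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression matrix with gene names in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT signature file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    signatures: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            signatures[parts[0]] = [g for g in parts[2:] if g]
    return signatures


def write_gmt(signatures: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
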