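"""Annotated genome container with FASTA/GFF3 I/O.

Internal coordinates are 0-based half-open throughout; GFF3 I/O converts from
the format's 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "contig", "start", "end", "strand"]


@dataclass
class AnnotatedGenome:
    """Contig sequences plus a stranded gene table.

    ``genes`` columns: gene_id, contig, start, end (0-based half-open), strand.
    """

    contigs: dict[str, str]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}
        genes = self.genes.reset_index(drop=True)
        missing = [c for c in GENE_COLUMNS if c not in genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        if genes["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        for row in genes.itertuples():
            if row.contig not in self.contigs:
                raise ValueError(f"gene {row.gene_id} on unknown contig {row.contig}")
            if not 0 <= row.start < row.end <= len(self.contigs[row.contig]):
                raise ValueError(f"gene {row.gene_id} interval out of contig bounds")
            if row.strand not in "+-":
                raise ValueError(f"gene {row.gene_id} has invalid strand {row.strand}")
        self.genes = genes

    def contig_length(self, name: str) -> int:
        return len(self.contigs[name])

    def gene(self, gene_id: str) -> pd.Series:
        rows = self.genes[self.genes["gene_id"] == gene_id]
        if rows.empty:
            raise KeyError(gene_id)
        return rows.iloc[0]

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path) -> "AnnotatedGenome":
        from Bio import SeqIO
        import gffutils

        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        db = gffutils.create_db(
            str(gff3), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        rows = []
        for feat in db.all_features(featuretype="CDS", order_by=("seqid", "start")):
            gene_id = (
                feat.attributes.get("locus_tag", [None])[0]
                or feat.attributes.get("ID", [feat.id])[0]
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "contig": feat.seqid,
                    "start": feat.start - 1,  # GFF3 is 1-based inclusive
                    "end": feat.end,
                    "strand": feat.strand,
                }
            )
        return cls(contigs=contigs, genes=pd.DataFrame(rows, columns=GENE_COLUMNS))

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path, source: str = "regumine") -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.contigs.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for row in self.genes.itertuples():
                fh.write(
                    "\t".join(
                        [
                            row.contig,
                            source,
                            "CDS",
                            str(row.start + 1),
                            str(row.end),
                            ".",
                            row.strand,
                            "0",
                            f"ID=cds-{row.gene_id};locus_tag={row.gene_id}",
                        ]
                    )
                    + "\n"
                )


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a disjoint sorted set."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def complement_intervals(
    intervals: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Complement of a merged interval set within [0, length)."""
    out = []
    prev = 0
    for start, end in intervals:
        if start > prev:
            out.append((prev, start))
        prev = max(prev, end)
    if prev < length:
        out.append((prev, length))
    return out


def interval_mask(intervals: list[tuple[int, int]], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        mask[max(0, start) : min(length, end)] = True
    return mask
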