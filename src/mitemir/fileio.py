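"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; GFF3 is the small, fixed feature vocabulary
this pipeline itself emits (gene, mRNA, exon, CDS, five_prime_UTR,
three_prime_UTR, MITE, sRNA cluster), with 1-based inclusive coordinates.
Collapsed sRNA FASTA uses the ``>name_xCOUNT`` header convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._types import MiteAnnotation, MiteElement


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_mite_fasta(path: str | Path, curated_prefixes: tuple[str, ...] = ("DTT_", "DTA_", "DTC_", "DTH_", "DTM_")) -> list[MiteElement]:
    """Read a MITE candidate/library FASTA.

    Elements whose id starts with a curated-database superfamily prefix
    (Stowaway/Tourist-style ``DTT_`` etc.) are marked ``curated``; all other
    ids are treated as de-novo discoveries.
    """
    out = []
    for name, seq in read_fasta(path).items():
        source = "curated" if name.startswith(curated_prefixes) else "de_novo"
        out.append(MiteElement(id=name, sequence=seq, source=source))
    return out


_COLLAPSED = re.compile(r"_x(\d+)$")


def read_collapsed_fasta(path: str | Path) -> list[tuple[str, int]]:
    """Collapsed sRNA reads as (sequence, count); header ``>read_7_x53``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COLLAPSED.search(rec.id)
        count = int(m.group(1)) if m else 1
        out.append((str(rec.seq).upper(), count))
    return out


def write_collapsed_fasta(reads: list[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(reads, 1):
            fh.write(f">read_{i}_x{count}\n{seq}\n")


# ---------------------------------------------------------------- GFF3

@dataclass
class GffFeature:
    chrom: str
    source: str
    type: str
    start: int  # 1-based inclusive
    end: int
    score: str
    strand: str
    frame: str
    attributes: dict[str, str] = field(default_factory=dict)

    def attribute_string(self) -> str:
        return ";".join(f"{k}={v}" for k, v in self.attributes.items())


def write_gff3(features: list[GffFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [f.chrom, f.source, f.type, str(f.start), str(f.end),
                     f.score, f.strand, f.frame, f.attribute_string()]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GffFeature]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            for item in cols[8].split(";"):
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            out.append(
                GffFeature(cols[0], cols[1], cols[2], int(cols[3]), int(cols[4]),
                           cols[5], cols[6], cols[7], attrs)
            )
    return out


def mite_annotations_to_gff(annotations: list[MiteAnnotation]) -> list[GffFeature]:
    return [
        GffFeature(
            a.chrom, "mitemir", "MITE", a.start, a.end, f"{a.identity:.1f}", a.strand, ".",
            {"ID": f"{a.mite_id}_{a.chrom}_{a.start}", "mite_id": a.mite_id,
             "identity": f"{a.identity:.1f}", "align_length": str(a.align_length)},
        )
        for a in annotations
    ]


def gff_to_mite_annotations(features: list[GffFeature]) -> list[MiteAnnotation]:
    return [
        MiteAnnotation(f.chrom, f.start, f.end, f.strand, f.attributes["mite_id"],
                       float(f.attributes["identity"]), int(f.attributes["align_length"]))
        for f in features
        if f.type == "MITE"
    ]


# ---------------------------------------------------------------- gene models

@dataclass
class TranscriptModel:
    """A transcript with its exon blocks and UTR/CDS segmentation.

    Exon blocks are genomic 1-based inclusive intervals in transcription
    order; segment lengths are in spliced transcript coordinates.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    utr5_len: int
    cds_len: int
    utr3_len: int

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def region_of(self, position: int) -> str:
        """Region label of a 1-based transcript position."""
        if position < 1 or position > self.length:
            raise ValueError(f"position {position} outside transcript {self.transcript_id}")
        if position <= self.utr5_len:
            return "five_prime_UTR"
        if position <= self.utr5_len + self.cds_len:
            return "CDS"
        return "three_prime_UTR"

    def to_genomic(self, position: int) -> int:
        """Lift a 1-based transcript position to a genomic position."""
        if position < 1 or position > self.length:
            raise ValueError(f"position {position} outside transcript {self.transcript_id}")
        remaining = position
        blocks = self.exons if self.strand == "+" else list(reversed(self.exons))
        for s, e in blocks:
            size = e - s + 1
            if remaining <= size:
                return s + remaining - 1 if self.strand == "+" else e - remaining + 1
            remaining -= size
        raise AssertionError("unreachable")

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        parts = [chrom_seq[s - 1 : e] for s, e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            from .align import revcomp

            seq = revcomp(seq)
        return seq


def transcript_models_from_gff(features: list[GffFeature]) -> dict[str, TranscriptModel]:
    """Assemble TranscriptModels from gene/mRNA/exon/CDS/UTR features."""
    mrnas = {f.attributes["ID"]: f for f in features if f.type == "mRNA"}
    children: dict[str, list[GffFeature]] = {tid: [] for tid in mrnas}
    for f in features:
        parent = f.attributes.get("Parent")
        if parent in children and f.type in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
            children[parent].append(f)
    models = {}
    for tid, mrna in mrnas.items():
        feats = children[tid]
        exons = sorted((f.start, f.end) for f in feats if f.type == "exon")
        if mrna.strand == "-":
            exons = list(reversed(exons))
        utr5 = sum(f.end - f.start + 1 for f in feats if f.type == "five_prime_UTR")
        cds = sum(f.end - f.start + 1 for f in feats if f.type == "CDS")
        utr3 = sum(f.end - f.start + 1 for f in feats if f.type == "three_prime_UTR")
        models[tid] = TranscriptModel(
            tid, mrna.attributes.get("Parent", tid), mrna.chrom, mrna.strand,
            exons, utr5, cds, utr3,
        )
    return models


# ---------------------------------------------------------------- degradome

def read_degradome_tsv(path: str | Path) -> pd.DataFrame:
    """Degradome 5'-end counts: columns transcript_id, position, count."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "position": int, "count": int})
    expected = {"transcript_id", "position", "count"}
    if set(df.columns) != expected:
        raise ValueError(f"degradome TSV must have columns {sorted(expected)}")
    return df


def write_degradome_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
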