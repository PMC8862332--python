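"""Shared domain types for the MITE-miRNA pipeline.

Coordinates are 1-based inclusive wherever a type faces GFF or report files;
0-based half-open slices are allowed internally but never leave a module.
"""

from __future__ import annotations

from dataclasses import dataclass, field


VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class MiteElement:
    """A consensus MITE sequence (library member)."""

    id: str
    sequence: str
    source: str = "de_novo"  # "curated" | "de_novo"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"MITE element {self.id!r} has empty sequence")
        bad = set(self.sequence.upper()) - VALID_NT
        if bad:
            raise ValueError(f"MITE element {self.id!r} has non-ACGTN characters: {bad}")
        if self.source not in ("curated", "de_novo"):
            raise ValueError(f"invalid source {self.source!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MiteAnnotation:
    """One genomic copy of a library MITE (1-based inclusive coords)."""

    chrom: str
    start: int
    end: int
    strand: str
    mite_id: str
    identity: float  # percent, 0-100
    align_length: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start for {self.mite_id} at {self.chrom}:{self.start}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReadAlignment:
    """A collapsed sRNA read placed on the genome."""

    sequence: str
    chrom: str
    start: int  # 1-based leftmost genomic position
    strand: str
    count: int = 1
    n_placements: int = 1
    library: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("read count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length - 1


INVALID = "INVALID"


@dataclass
class SrnaCluster:
    """A genomic sRNA cluster with its aligned read multiset."""

    chrom: str
    start: int
    end: int
    alignments: list[ReadAlignment] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(a.count for a in self.alignments)

    @property
    def top_strand_fraction(self) -> float:
        tot = self.total_reads
        if tot == 0:
            return 0.0
        return sum(a.count for a in self.alignments if a.strand == "+") / tot

    @property
    def major_rna(self) -> ReadAlignment | None:
        """Most abundant read; ties broken by lexicographically smallest sequence,
        then leftmost position."""
        if not self.alignments:
            return None
        return min(self.alignments, key=lambda a: (-a.count, a.sequence, a.start))

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA secondary structure in dot-bracket notation.

    ``pairs[i]`` is the partner index of position i, or -1 if unpaired
    (0-based).  Only A-U, G-C and G-U pairs, minimum hairpin loop of 3.
    """

    sequence: str
    dotbracket: str
    pairs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket) or len(self.sequence) != len(self.pairs):
            raise ValueError("structure fields have inconsistent lengths")
        for i, j in enumerate(self.pairs):
            if j >= 0 and self.pairs[j] != i:
                raise ValueError("pair table not mutually consistent")

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pairs) if j > i)


@dataclass
class MirnaLocus:
    """Outcome of the validation ladder for one sRNA cluster."""

    cluster: SrnaCluster
    result_code: str  # N1..N15 or Y
    precursor_start: int = 0  # genomic, 1-based; 0 if folding never reached
    precursor_seq: str = ""
    structure: SecondaryStructure | None = None
    mature_seq: str = ""
    mature_start: int = 0  # genomic, 1-based
    star_seq: str = ""
    star_start: int = 0
    strand: str = "+"
    dicer_call: str = INVALID
    precision: float = 0.0

    @property
    def is_valid(self) -> bool:
        return self.result_code == "Y"


@dataclass
class MirnaRecord:
    """A validated miRNA with MITE homology, catalog and context annotation
    (one row of the MITE-derived miRNA report)."""

    name: str
    locus: str  # "chrom:start-end"
    strand: str
    mature: str  # RNA alphabet (U not T)
    mite_id: str | None = None
    known_annotation: str | None = None
    contexts: tuple[str, ...] = ("intergenic",)
    gene_ids: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.mature)


@dataclass
class DegradomeProfile:
    """Per-position 5'-end read counts on one transcript (1-based positions)."""

    transcript_id: str
    counts: "object"  # numpy int array, index 0 = position 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TargetSite:
    """A miRNA cleavage site with both evidence streams attached."""

    mirna_id: str
    transcript_id: str
    cleavage_position: int  # 1-based transcript coordinate
    expectation: float
    category: int
    p_value: float
    region: str = ""  # five_prime_UTR | CDS | three_prime_UTR
    mite_in_target: str | None = None
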