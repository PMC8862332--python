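"""MITE homology of miRNA production loci, known-miRNA matching and
genomic-context labelling.

A validated miRNA locus is MITE-derived when its precursor-containing
window shows >= 80% identity over >= 80% of the sequence to a library
element (the 80/80 rule).  The coverage denominator defaults to the
shorter of window and element: precursor windows can far exceed element
lengths, which makes the element-side denominator the only reading that
can ever be satisfied for long windows; the denominator is configurable.

Context labels come from the gene annotation expanded with derived
introns (exon complement within the gene span) and promoters (the
strand-aware 2000-nt window upstream of each gene, truncated at the
chromosome start).  A locus overlapping nothing is intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._types import MirnaLocus, MirnaRecord, MiteElement
from .align import edit_stats, find_local_hits, revcomp
from .fileio import GffFeature

PROMOTER_LENGTH = 2000
MIN_IDENTITY_PCT = 80.0
MIN_COVERAGE = 0.8
MAX_KNOWN_EDITS = 4
KNOWN_LENGTH_SLACK = 4

CONTEXT_LABELS = ("intergenic", "promoter", "intron", "exon", "five_prime_UTR", "three_prime_UTR")


def classify_mite_derived(
    window_seq: str,
    library: list[MiteElement],
    min_identity: float = MIN_IDENTITY_PCT,
    min_coverage: float = MIN_COVERAGE,
    coverage_denominator: str = "shorter",
) -> tuple[MiteElement, float] | None:
    """Best qualifying MITE homology of a precursor window, or None.

    A hit qualifies when identity >= ``min_identity`` and the alignment
    covers >= ``min_coverage`` of the denominator length (``"shorter"`` of
    window/element, or ``"element"``).  Ties: higher identity, longer
    alignment, smaller element id.
    """
    if coverage_denominator not in ("shorter", "element"):
        raise ValueError("coverage_denominator must be 'shorter' or 'element'")
    hits: list[tuple[float, int, str, MiteElement]] = []
    for element in library:
        denom = (
            min(len(window_seq), element.length)
            if coverage_denominator == "shorter"
            else element.length
        )
        for query in (element.sequence, revcomp(element.sequence)):
            for hit in find_local_hits(query, window_seq):
                if hit.identity >= min_identity and hit.n_columns >= min_coverage * denom:
                    hits.append((hit.identity, hit.n_columns, element.id, element))
    if not hits:
        return None
    best = min(hits, key=lambda h: (-h[0], -h[1], h[2]))
    return best[3], best[0]


def match_known_mirna(mature: str, catalog: dict[str, str]) -> list[str]:
    """Catalog entries matching a mature sequence: local alignments with at
    most 4 mismatches + gaps and length >= the known mature's length - 4."""
    mature_dna = mature.upper().replace("U", "T")
    out = []
    for name in sorted(catalog):
        known = catalog[name].upper().replace("U", "T")
        if not 18 <= len(known) <= 26:
            continue
        columns, edits = edit_stats(mature_dna, known)
        if edits <= MAX_KNOWN_EDITS and columns >= len(known) - KNOWN_LENGTH_SLACK:
            out.append(name)
    return out


@dataclass(frozen=True)
class _Interval:
    chrom: str
    start: int
    end: int
    label: str
    gene_id: str


def build_context_intervals(
    features: list[GffFeature],
    promoter_length: int = PROMOTER_LENGTH,
) -> list[_Interval]:
    """Expand a gene annotation into labelled context intervals.

    Introns are derived per gene as the exon complement within the gene
    span (using the longest transcript); promoters are the strand-aware
    ``promoter_length`` window upstream of the gene start, truncated at the
    chromosome start.  Overlap with another gene does not cancel a
    promoter.
    """
    intervals: list[_Interval] = []
    genes = [f for f in features if f.type == "gene"]
    mrnas_by_gene: dict[str, list[GffFeature]] = {}
    for f in features:
        if f.type == "mRNA":
            mrnas_by_gene.setdefault(f.attributes.get("Parent", ""), []).append(f)
    exons_by_mrna: dict[str, list[tuple[int, int]]] = {}
    utrs: list[GffFeature] = []
    for f in features:
        if f.type == "exon":
            exons_by_mrna.setdefault(f.attributes.get("Parent", ""), []).append((f.start, f.end))
        elif f.type in ("five_prime_UTR", "three_prime_UTR"):
            utrs.append(f)

    for gene in genes:
        gid = gene.attributes.get("ID", "")
        mrnas = mrnas_by_gene.get(gid, [])
        # longest transcript's exons define the intron structure
        longest = max(mrnas, key=lambda m: m.end - m.start, default=None)
        exons = sorted(exons_by_mrna.get(longest.attributes["ID"], [])) if longest else []
        for s, e in exons:
            intervals.append(_Interval(gene.chrom, s, e, "exon", gid))
        cursor = gene.start
        for s, e in exons:
            if s > cursor:
                intervals.append(_Interval(gene.chrom, cursor, s - 1, "intron", gid))
            cursor = max(cursor, e + 1)
        if cursor <= gene.end:
            intervals.append(_Interval(gene.chrom, cursor, gene.end, "intron", gid))
        if gene.strand == "+":
            p_start = max(1, gene.start - promoter_length)
            p_end = gene.start - 1
        else:
            p_start = gene.end + 1
            p_end = gene.end + promoter_length
        if p_end >= p_start:
            intervals.append(_Interval(gene.chrom, p_start, p_end, "promoter", gid))
    for f in utrs:
        gid = f.attributes.get("Parent", "").rsplit(".", 1)[0]
        intervals.append(_Interval(f.chrom, f.start, f.end, f.type, gid))
    return intervals


def label_context(
    chrom: str,
    start: int,
    end: int,
    context_intervals: list[_Interval],
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(context labels, gene ids) of a genomic locus; ({'intergenic'}, ())
    when nothing overlaps."""
    labels: list[str] = []
    genes: list[str] = []
    for iv in context_intervals:
        if iv.chrom == chrom and iv.start <= end and start <= iv.end:
            if iv.label not in labels:
                labels.append(iv.label)
            if iv.gene_id and iv.gene_id not in genes:
                genes.append(iv.gene_id)
    if not labels:
        return ("intergenic",), ()
    order = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}
    return tuple(sorted(labels, key=lambda l: order.get(l, 99))), tuple(sorted(genes))


def build_mirna_records(
    loci: list[MirnaLocus],
    library: list[MiteElement],
    features: list[GffFeature],
    known_catalog: dict[str, str] | None = None,
    promoter_length: int = PROMOTER_LENGTH,
    exclude_exon_for_intronic: bool = False,
) -> list[MirnaRecord]:
    """One report row per valid (Y-coded) miRNA locus: MITE homology,
    known-miRNA annotation, genomic context and host genes."""
    intervals = build_context_intervals(features, promoter_length)
    records = []
    n = 0
    for locus in loci:
        if not locus.is_valid:
            continue
        n += 1
        hit = classify_mite_derived(locus.precursor_seq, library)
        known = match_known_mirna(locus.mature_seq, known_catalog) if known_catalog else []
        labels, genes = label_context(locus.cluster.chrom, locus.cluster.start, locus.cluster.end, intervals)
        if exclude_exon_for_intronic and "intron" in labels:
            labels = tuple(l for l in labels if l != "exon")
        records.append(
            MirnaRecord(
                name=f"MITE_miRNA_{n}" if hit else f"miRNA_{n}",
                locus=locus.cluster.name,
                strand=locus.strand,
                mature=locus.mature_seq.replace("T", "U"),
                mite_id=hit[0].id if hit else None,
                known_annotation=",".join(known) if known else None,
                contexts=labels,
                gene_ids=genes,
            )
        )
    return records
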