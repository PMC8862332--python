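"""Non-redundant MITE library construction and genome-wide annotation.

The library is built by greedy centroid clustering at a fixed identity
threshold (default 0.8): elements are processed in canonical order and
join the first cluster whose representative they match; curated-database
members take precedence as representatives.  Genome annotation runs a
local-alignment search of every library element against both strands and
then applies the copy filters: genomic span within [50, 1100] nt,
identity >= 80%, alignment covering >= 80% of the element, and
deduplication of hits whose start AND end positions lie within 5 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from ._types import MiteAnnotation, MiteElement
from .align import find_local_hits, pairwise_identity, revcomp
from .fileio import mite_annotations_to_gff, write_gff3

MIN_COPY_LEN = 50
MAX_COPY_LEN = 1100
MIN_IDENTITY_PCT = 80.0
MIN_COVERAGE = 0.8
DEDUP_DISTANCE = 5


@dataclass
class MiteCluster:
    representative: MiteElement
    members: list[MiteElement]


def _canonical_order(elements: list[MiteElement]) -> list[MiteElement]:
    # curated members first so they found clusters and become representatives,
    # then by id for order determinism
    return sorted(elements, key=lambda e: (e.source != "curated", e.id))


def cluster_mites(elements: list[MiteElement], threshold: float = 0.8) -> list[MiteCluster]:
    """Greedy centroid clustering of MITE candidates at an identity threshold.

    Processing order is canonical (curated elements first, then by id), so
    clustering does not depend on input order.  The representative of a
    cluster is its lowest-id curated member if one exists, otherwise the
    founding member.
    """
    if not elements:
        raise ValueError("cluster_mites requires at least one element")
    clusters: list[MiteCluster] = []
    for element in _canonical_order(elements):
        placed = False
        for cluster in clusters:
            if pairwise_identity(element.sequence, cluster.representative.sequence) >= threshold:
                cluster.members.append(element)
                placed = True
                break
        if not placed:
            clusters.append(MiteCluster(representative=element, members=[element]))
    for cluster in clusters:
        curated = sorted((m for m in cluster.members if m.source == "curated"), key=lambda m: m.id)
        if curated:
            cluster.representative = curated[0]
    return clusters


def cluster_representatives(elements: list[MiteElement], threshold: float = 0.8) -> list[MiteElement]:
    return [c.representative for c in cluster_mites(elements, threshold)]


def annotate_genome(
    genome: dict[str, str],
    library: list[MiteElement],
    min_identity: float = MIN_IDENTITY_PCT,
    min_coverage: float = MIN_COVERAGE,
    min_len: int = MIN_COPY_LEN,
    max_len: int = MAX_COPY_LEN,
) -> list[MiteAnnotation]:
    """All filtered MITE copies of the library elements in a genome.

    Both strands are searched (the minus strand by aligning the
    reverse-complemented element on the plus strand, so coordinates are
    always plus-strand 1-based inclusive).
    """
    raw: list[MiteAnnotation] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        if not seq:
            continue
        for element in library:
            for strand in "+-":
                query = element.sequence if strand == "+" else revcomp(element.sequence)
                for hit in find_local_hits(query, seq):
                    span = hit.t_end - hit.t_start
                    if span < min_len or span > max_len:
                        continue
                    if hit.identity < min_identity:
                        continue
                    if hit.n_columns < min_coverage * element.length:
                        continue
                    raw.append(
                        MiteAnnotation(chrom, hit.t_start + 1, hit.t_end, strand,
                                       element.id, hit.identity, hit.n_columns)
                    )
    return deduplicate_annotations(raw)


def deduplicate_annotations(annotations: list[MiteAnnotation]) -> list[MiteAnnotation]:
    """Collapse hits that describe the same locus: two hits whose starts AND
    ends both differ by < DEDUP_DISTANCE nt are duplicates; the
    higher-identity one is kept (ties: lexicographically smaller mite_id)."""
    order = sorted(annotations, key=lambda a: (-a.identity, a.mite_id, a.chrom, a.start, a.end))
    kept: list[MiteAnnotation] = []
    for a in order:
        dup = any(
            k.chrom == a.chrom
            and abs(k.start - a.start) < DEDUP_DISTANCE
            and abs(k.end - a.end) < DEDUP_DISTANCE
            for k in kept
        )
        if not dup:
            kept.append(a)
    return sorted(kept, key=lambda a: (a.chrom, a.start, a.end, a.mite_id))


def write_mite_gff(annotations: list[MiteAnnotation], path: str | Path) -> None:
    ordered = sorted(annotations, key=lambda a: (a.chrom, a.start, a.end, a.mite_id))
    write_gff3(mite_annotations_to_gff(ordered), path)
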