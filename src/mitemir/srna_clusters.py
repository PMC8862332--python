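"""Placement of collapsed sRNA reads and sRNA cluster discovery.

Reads are placed by exact matching on both strands (every placement of a
multi-mapping read is reported with its placement count).  De-novo
clusters are islands of read alignments whose +/-75 nt padded intervals
overlap; islands with fewer than 10 reads (multiplicity-weighted) are
discarded.  A second, interval-driven pass quantifies user-supplied loci
(the MITE-annotation second pass) under the same read threshold.
"""

from __future__ import annotations

import warnings

from ._types import INVALID, ReadAlignment, SrnaCluster
from .align import revcomp
from .fileio import GffFeature

MIN_READS = 10
PAD = 75
DICER_MIN = 20
DICER_MAX = 24


def place_reads(
    reads: list[tuple[str, int]],
    genome: dict[str, str],
    library: str = "",
) -> list[ReadAlignment]:
    """Exact-match placements of collapsed reads on both genome strands.

    Reads containing non-ACGT characters are skipped with a warning.  A
    read found at k sites is reported k times, each with n_placements=k.
    """
    placements: list[ReadAlignment] = []
    chroms = sorted(genome)
    for seq, count in reads:
        seq = seq.upper().replace("U", "T")
        if set(seq) - set("ACGT"):
            warnings.warn(f"skipping read with non-ACGT characters: {seq!r}")
            continue
        sites: list[tuple[str, int, str]] = []
        rc = revcomp(seq)
        for chrom in chroms:
            target = genome[chrom]
            for query, strand in ((seq, "+"), (rc, "-")):
                pos = target.find(query)
                while pos != -1:
                    sites.append((chrom, pos + 1, strand))
                    pos = target.find(query, pos + 1)
        for chrom, start, strand in sites:
            placements.append(
                ReadAlignment(seq, chrom, start, strand, count, len(sites), library)
            )
    placements.sort(key=lambda a: (a.chrom, a.start, a.strand, a.sequence))
    return placements


def find_clusters(
    alignments: list[ReadAlignment],
    min_reads: int = MIN_READS,
    pad: int = PAD,
) -> list[SrnaCluster]:
    """De-novo clusters: merge alignments whose padded intervals overlap into
    islands, then drop islands with fewer than ``min_reads`` total reads.
    Cluster bounds are the unpadded min/max of member coordinates."""
    clusters: list[SrnaCluster] = []
    by_chrom: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda a: (a.start, a.end, a.sequence))
        island: list[ReadAlignment] = []
        island_end = -1
        for a in members:
            if island and a.start - pad > island_end + pad:
                clusters.append(_island_to_cluster(chrom, island))
                island = []
            island.append(a)
            island_end = max(island_end, a.end)
        if island:
            clusters.append(_island_to_cluster(chrom, island))
    return [c for c in clusters if c.total_reads >= min_reads]


def _island_to_cluster(chrom: str, members: list[ReadAlignment]) -> SrnaCluster:
    return SrnaCluster(
        chrom=chrom,
        start=min(a.start for a in members),
        end=max(a.end for a in members),
        alignments=list(members),
    )


def quantify_loci(
    alignments: list[ReadAlignment],
    intervals: list[GffFeature],
    min_reads: int = MIN_READS,
) -> list[SrnaCluster]:
    """One cluster per supplied interval, from the alignments falling fully
    inside it; intervals below the read threshold are dropped.  Overlapping
    intervals are quantified independently."""
    out = []
    for iv in intervals:
        if iv.end < iv.start:
            raise ValueError(f"malformed interval {iv.attributes.get('ID', iv.chrom)}")
        members = [
            a for a in alignments
            if a.chrom == iv.chrom and a.start >= iv.start and a.end <= iv.end
        ]
        if not members:
            continue
        cluster = _island_to_cluster(iv.chrom, members)
        if cluster.total_reads >= min_reads:
            out.append(cluster)
    return out


def dicer_call(
    cluster: SrnaCluster,
    dicermin: int = DICER_MIN,
    dicermax: int = DICER_MAX,
) -> str:
    """Modal in-range read length if >= 80% of reads fall in the Dicer size
    range, else INVALID."""
    total = cluster.total_reads
    if total < 1:
        raise ValueError("dicer_call requires a cluster with reads")
    in_range: dict[int, int] = {}
    n_in = 0
    for a in cluster.alignments:
        if dicermin <= a.length <= dicermax:
            n_in += a.count
            in_range[a.length] = in_range.get(a.length, 0) + a.count
    if n_in / total < 0.8:
        return INVALID
    modal = min(in_range.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return str(modal)


def deduplicate_clusters(clusters: list[SrnaCluster], tolerance: int = 0) -> list[SrnaCluster]:
    """Collapse clusters duplicated in (major RNA sequence, chrom, start, end);
    the de-novo and interval-driven passes both report shared loci.

    With ``tolerance`` > 0, clusters sharing chrom and major RNA whose
    bounds differ by at most that many nt are also considered the same
    locus (interval-pass clusters clip reads at interval edges, so their
    bounds can sit a few nt inside the de-novo island's); the cluster with
    more reads, then the wider one, is kept."""
    ordered = sorted(
        clusters,
        key=lambda c: (-c.total_reads, -(c.end - c.start), c.chrom, c.start, c.end),
    )
    kept: list[SrnaCluster] = []
    for c in ordered:
        major = c.major_rna
        major_seq = major.sequence if major else ""
        dup = any(
            k.chrom == c.chrom
            and (k.major_rna.sequence if k.major_rna else "") == major_seq
            and abs(k.start - c.start) <= tolerance
            and abs(k.end - c.end) <= tolerance
            for k in kept
        )
        if not dup:
            kept.append(c)
    return sorted(kept, key=lambda c: (c.chrom, c.start, c.end))
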