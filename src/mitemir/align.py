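"""Pairwise alignment helpers.

All scoring in the pipeline uses one fixed scheme (match +1, mismatch -1,
gap -2); identity is always (identical columns) / (total alignment columns,
gap columns included).  Genome-scale searches use exact k-mer seeding to
locate candidate windows and then run the same optimal local alignment
inside each window, so results at pipeline scale equal a full scan.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from Bio import Align

MATCH, MISMATCH, GAP = 1.0, -1.0, -2.0

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP
    aligner.extend_gap_score = GAP
    return aligner


_GLOBAL = _make_aligner("global")
_LOCAL = _make_aligner("local")


def _column_counts(alignment) -> tuple[int, int, int]:
    """(identities, mismatches, gap columns) over the aligned region."""
    counts = alignment.counts()
    return counts.identities, counts.mismatches, counts.gaps


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences, in [0, 1].

    Identity is counted over all alignment columns of an optimal global
    alignment, gap columns included (the ``--iddef 1`` convention).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    alignment = _GLOBAL.align(a, b)[0]
    ident, mism, gaps = _column_counts(alignment)
    columns = ident + mism + gaps
    return ident / columns if columns else 0.0


@dataclass(frozen=True)
class LocalHit:
    """A local alignment of a query inside a target sequence.

    ``t_start``/``t_end`` are a 0-based half-open span on the target.
    """

    t_start: int
    t_end: int
    identity: float  # percent 0-100
    n_columns: int
    score: float


def local_align(query: str, target: str) -> LocalHit | None:
    """Best local alignment of query vs target under the fixed scheme."""
    if not query or not target:
        return None
    alignments = _LOCAL.align(target.upper(), query.upper())
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    alignment = alignments[0]
    ident, mism, gaps = _column_counts(alignment)
    columns = ident + mism + gaps
    if columns == 0:
        return None
    t_blocks = alignment.aligned[0]
    t_start = int(t_blocks[0][0])
    t_end = int(t_blocks[-1][1])
    return LocalHit(t_start, t_end, 100.0 * ident / columns, columns, float(alignments.score))


def _seed_bands(query: str, target: str, k: int, diag_tol: int) -> list[tuple[int, int]]:
    """Candidate target windows (0-based half-open) from exact k-mer seeds."""
    qkmers: dict[str, list[int]] = defaultdict(list)
    for q in range(len(query) - k + 1):
        qkmers[query[q : q + k]].append(q)
    hits: list[tuple[int, int]] = []  # (diagonal, target pos)
    for p in range(len(target) - k + 1):
        positions = qkmers.get(target[p : p + k])
        if positions:
            for q in positions:
                hits.append((p - q, p))
    if not hits:
        return []
    hits.sort()
    margin = len(query) + 25
    bands: list[tuple[int, int]] = []
    cur_d, cur_ps = hits[0][0], [hits[0][1]]
    groups: list[list[int]] = []

    def flush(ps: list[int]) -> None:
        ps.sort()
        run = [ps[0]]
        for p in ps[1:]:
            if p - run[-1] > margin:
                groups.append(run)
                run = [p]
            else:
                run.append(p)
        groups.append(run)

    for d, p in hits[1:]:
        if d - cur_d <= diag_tol:
            cur_ps.append(p)
        else:
            flush(cur_ps)
            cur_d, cur_ps = d, [p]
    flush(cur_ps)
    for run in groups:
        start = max(0, run[0] - margin)
        end = min(len(target), run[-1] + k + margin)
        bands.append((start, end))
    # merge overlapping windows
    bands.sort()
    merged = [bands[0]]
    for s, e in bands[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def find_local_hits(query: str, target: str, k: int = 11, diag_tol: int = 20) -> list[LocalHit]:
    """All local-alignment hits of query in target (plus strand of target).

    Each exact-k-mer seed band yields at most one hit (the optimal local
    alignment inside the band's window).
    """
    query, target = query.upper(), target.upper()
    if len(query) < k or len(target) < k:
        hit = local_align(query, target)
        return [hit] if hit else []
    out = []
    for w_start, w_end in _seed_bands(query, target, k, diag_tol):
        hit = local_align(query, target[w_start:w_end])
        if hit is not None:
            out.append(
                LocalHit(hit.t_start + w_start, hit.t_end + w_start, hit.identity, hit.n_columns, hit.score)
            )
    return out


def edit_stats(query: str, subject: str) -> tuple[int, int]:
    """(alignment columns, mismatches + gap columns) of the best local
    alignment of query vs subject; (0, 0) if nothing aligns."""
    hit_alns = _LOCAL.align(subject.upper(), query.upper())
    if len(hit_alns) == 0 or hit_alns.score <= 0:
        return 0, 0
    ident, mism, gaps = _column_counts(hit_alns[0])
    return ident + mism + gaps, mism + gaps
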