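"""miRNA target prediction and degradome validation.

Two independent evidence streams are computed and intersected:

* complementarity: every transcript window is scored with a penalty-sum
  expectation (mismatch 1.0, G:U wobble 0.5, gap 2.0 open / 0.5 extend,
  all multiplied by 1.5 inside the seed region, miRNA positions 2-13);
  windows at or under the cutoff (default 5.0) are candidate sites, with
  the predicted cleavage position at the transcript base paired to miRNA
  position 10;
* degradome: the 5'-end count at the candidate position is categorized
  against the rest of the transcript (0 unique maximum, 1 tied maximum,
  2 above the median of positive counts, 3 at or below it, 4 a single
  read) and assigned a permutation p-value from composition-preserving
  shuffles of the miRNA.

Only sites reported by both streams, with category <= 3 and p < 0.05,
are retained.  MITE insertions covering the cleavage location are then
detected with the 80/80 homology rule.

The category definitions and the permutation null re-specify the
behaviour of the classical degradome pipeline in an explicit, seeded
form; they are documented approximations, not bit-compatible
re-implementations of any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._types import DegradomeProfile, MiteElement, TargetSite
from .align import find_local_hits, revcomp
from .fileio import TranscriptModel

ALPHA = 0.05
MAX_CATEGORY = 3


@dataclass(frozen=True)
class ScoringConfig:
    """The five penalty constants of the expectation score plus the seed
    window and multiplier."""

    mismatch: float = 1.0
    gu_wobble: float = 0.5
    gap_open: float = 2.0
    gap_extend: float = 0.5
    seed_multiplier: float = 1.5
    seed_start: int = 2  # miRNA positions (1-based, from the 5' end)
    seed_end: int = 13
    cutoff: float = 5.0

    def position_multiplier(self, pos: int) -> float:
        return self.seed_multiplier if self.seed_start <= pos <= self.seed_end else 1.0


_IDX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_IDX.get(b, 0) for b in seq.upper()], dtype=np.int8)


def _penalty_table(scoring: ScoringConfig) -> np.ndarray:
    """penalty[mirna_base, transcript_base] for an antiparallel pairing."""
    table = np.full((4, 4), scoring.mismatch)
    watson_crick = {(0, 3), (3, 0), (2, 1), (1, 2)}  # A-U/T, U-A, G-C, C-G
    wobble = {(2, 3), (3, 2)}  # G pairs U/T, U pairs G
    for m, t in watson_crick:
        table[m, t] = 0.0
    for m, t in wobble:
        table[m, t] = scoring.gu_wobble
    return table


def _multipliers(length: int, scoring: ScoringConfig) -> np.ndarray:
    return np.array([scoring.position_multiplier(i + 1) for i in range(length)])


def expectation_score(mirna: str, site: str, scoring: ScoringConfig | None = None) -> float:
    """Expectation (penalty sum) of a miRNA against one target site.

    The site is the transcript subsequence 5'->3'; the alignment is
    antiparallel (miRNA position 1 against the site's 3'-most base) and
    global over both sequences, gaps allowed.  0 = perfect pairing.
    """
    scoring = scoring or ScoringConfig()
    if not mirna or not site:
        raise ValueError("expectation_score requires non-empty sequences")
    m = _encode(mirna)
    t = _encode(site)[::-1]  # align antiparallel
    table = _penalty_table(scoring)
    L, S = len(m), len(t)
    mult = _multipliers(L, scoring)

    def gap_cost(pos: int, extending: bool) -> float:
        base = scoring.gap_extend if extending else scoring.gap_open
        return base * scoring.position_multiplier(min(max(pos, 1), L))

    INF = float("inf")
    # dp[j] over site prefix j for current miRNA prefix i; track gap state
    # via three matrices (match, gap-in-mirna, gap-in-site)
    M = np.full((L + 1, S + 1), INF)
    X = np.full((L + 1, S + 1), INF)  # gap in site (miRNA base unmatched)
    Y = np.full((L + 1, S + 1), INF)  # gap in miRNA (site base unmatched)
    M[0, 0] = 0.0
    for i in range(1, L + 1):
        X[i, 0] = min(M[i - 1, 0] + gap_cost(i, False), X[i - 1, 0] + gap_cost(i, True))
    for j in range(1, S + 1):
        Y[0, j] = min(M[0, j - 1] + gap_cost(1, False), Y[0, j - 1] + gap_cost(1, True))
    for i in range(1, L + 1):
        for j in range(1, S + 1):
            sub = table[m[i - 1], t[j - 1]] * mult[i - 1]
            M[i, j] = min(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = min(M[i - 1, j] + gap_cost(i, False), X[i - 1, j] + gap_cost(i, True))
            Y[i, j] = min(M[i, j - 1] + gap_cost(i, False), Y[i, j - 1] + gap_cost(i, True))
    return float(min(M[L, S], X[L, S], Y[L, S]))


def _gapless_scan(m_codes: np.ndarray, t_codes: np.ndarray, scoring: ScoringConfig) -> np.ndarray:
    """Gapless expectations of every window (one per start offset).

    Window w covers transcript offsets [w, w+L); miRNA position k pairs the
    window base at offset L-k (antiparallel).
    """
    L = len(m_codes)
    n_win = len(t_codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    table = _penalty_table(scoring)
    mult = _multipliers(L, scoring)
    out = np.zeros(n_win)
    for k in range(L):  # miRNA position k+1 pairs transcript offset w + L-1-k
        out += table[m_codes[k], t_codes[L - 1 - k : L - 1 - k + n_win]] * mult[k]
    return out


@dataclass(frozen=True)
class CandidateSite:
    mirna_id: str
    transcript_id: str
    cleavage_position: int  # 1-based
    expectation: float


def scan_transcripts(
    mirna_id: str,
    mirna_seq: str,
    transcripts: dict[str, str],
    scoring: ScoringConfig | None = None,
    refine_with_gaps: bool = True,
) -> list[CandidateSite]:
    """All candidate target sites of one miRNA with expectation <= cutoff.

    Windows are scored gaplessly first; windows near the cutoff are
    re-scored with the gapped alignment and the better (lower) expectation
    kept.  The cleavage position of the window starting at 0-based offset
    w is w + L - 9 (1-based), the base paired to miRNA position 10.
    """
    scoring = scoring or ScoringConfig()
    m_codes = _encode(mirna_seq)
    L = len(m_codes)
    out = []
    gap_margin = scoring.gap_open * scoring.seed_multiplier
    for tid in sorted(transcripts):
        t_codes = _encode(transcripts[tid])
        scores = _gapless_scan(m_codes, t_codes, scoring)
        for w in np.nonzero(scores <= scoring.cutoff + gap_margin)[0]:
            expectation = float(scores[w])
            if refine_with_gaps and expectation > 0:
                gapped = expectation_score(mirna_seq, transcripts[tid][w : w + L], scoring)
                expectation = min(expectation, gapped)
            if expectation <= scoring.cutoff:
                out.append(CandidateSite(mirna_id, tid, int(w) + L - 9, expectation))
    return out


def cleavage_category(profile: DegradomeProfile, position: int) -> int | None:
    """Degradome category of a 1-based transcript position; None when the
    position has no 5'-end signal (the site is dropped)."""
    counts = np.asarray(profile.counts)
    if not 1 <= position <= len(counts):
        raise ValueError(f"position {position} outside transcript {profile.transcript_id}")
    r = int(counts[position - 1])
    if r == 0:
        return None
    if r == 1:
        return 4
    maximum = int(counts.max())
    if r == maximum:
        return 0 if int((counts == maximum).sum()) == 1 else 1
    median = float(np.median(counts[counts > 0]))
    return 2 if r > median else 3


def cleavage_pvalue(
    mirna_seq: str,
    transcript_seq: str,
    profile: DegradomeProfile,
    position: int,
    observed_category: int,
    n_perm: int = 1000,
    seed: int = 0,
    scoring: ScoringConfig | None = None,
) -> float:
    """Permutation p-value of a candidate site.

    The null shuffles the miRNA (composition-preserving, seeded) ``n_perm``
    times; for each shuffle the best (lowest, gapless) expectation over all
    transcript positions whose degradome category is at or below the
    observed category is recorded, and

        p = (1 + #{shuffles with best <= observed}) / (n_perm + 1).
    """
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is 1/{n_perm + 1}")
    scoring = scoring or ScoringConfig()
    m_codes = _encode(mirna_seq)
    t_codes = _encode(transcript_seq)
    L = len(m_codes)
    counts = np.asarray(profile.counts)
    eligible = [
        p for p in range(1, len(counts) + 1)
        if (c := cleavage_category(profile, p)) is not None and c <= observed_category
    ]
    # windows whose predicted cleavage position is an eligible position
    # (cleavage = w + L - 9 for a window at 0-based offset w)
    windows = np.array([p - L + 9 for p in eligible], dtype=int)
    windows = windows[(windows >= 0) & (windows <= len(t_codes) - L)]
    if windows.size == 0:
        return 1.0
    table = _penalty_table(scoring)
    mult = _multipliers(L, scoring)
    win_mat = np.stack([t_codes[w : w + L][::-1] for w in windows])  # (n_win, L)
    obs_w = position - L + 9  # 0-based window start of the observed site
    obs_window = t_codes[obs_w : obs_w + L][::-1]
    observed = float((table[m_codes, obs_window] * mult).sum())
    rng = np.random.default_rng(seed)
    shuffles = np.stack([rng.permutation(m_codes) for _ in range(n_perm)])  # (n_perm, L)
    # expectations[s, w] = sum_k table[shuffles[s,k], win_mat[w,k]] * mult[k]
    expectations = (table[shuffles[:, None, :], win_mat[None, :, :]] * mult).sum(axis=2)
    best = expectations.min(axis=1)
    return float((1 + int((best <= observed + 1e-9).sum())) / (n_perm + 1))


def degradome_evidence(
    candidates: list[CandidateSite],
    transcripts: dict[str, str],
    profiles: dict[str, DegradomeProfile],
    mirnas: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    scoring: ScoringConfig | None = None,
) -> list[TargetSite]:
    """Attach degradome category and permutation p-value to candidate sites.

    Sites without 5'-end signal are dropped; category-4 sites keep p = 1
    (they can never pass the merged filter)."""
    out = []
    for cand in candidates:
        profile = profiles.get(cand.transcript_id)
        if profile is None:
            continue
        category = cleavage_category(profile, cand.cleavage_position)
        if category is None:
            continue
        if category <= MAX_CATEGORY:
            p = cleavage_pvalue(
                mirnas[cand.mirna_id], transcripts[cand.transcript_id], profile,
                cand.cleavage_position, category, n_perm, seed, scoring,
            )
        else:
            p = 1.0
        out.append(
            TargetSite(cand.mirna_id, cand.transcript_id, cand.cleavage_position,
                       cand.expectation, category, p)
        )
    return out


def degradome_evidence_multilibrary(
    candidates: list[CandidateSite],
    transcripts: dict[str, str],
    profiles_by_library: dict[str, dict[str, DegradomeProfile]],
    mirnas: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    scoring: ScoringConfig | None = None,
) -> list[TargetSite]:
    """Degradome evidence over several libraries.

    Each library is evaluated independently (with its own derived seed)
    and, for every site, the best-supported record — lowest p-value, then
    lowest category — is reported."""
    best: dict[tuple[str, str, int], TargetSite] = {}
    for i, lib in enumerate(sorted(profiles_by_library)):
        sites = degradome_evidence(
            candidates, transcripts, profiles_by_library[lib], mirnas,
            n_perm=n_perm, seed=seed + i, scoring=scoring,
        )
        for site in sites:
            key = (site.mirna_id, site.transcript_id, site.cleavage_position)
            cur = best.get(key)
            if cur is None or (site.p_value, site.category) < (cur.p_value, cur.category):
                best[key] = site
    return sorted(best.values(), key=lambda s: (s.mirna_id, s.transcript_id, s.cleavage_position))


def merge_evidence(
    degradome_sites: list[TargetSite],
    homology_sites: list[CandidateSite],
    scoring: ScoringConfig | None = None,
    alpha: float = ALPHA,
) -> list[TargetSite]:
    """Sites reported by both streams (exact (miRNA, transcript, position)
    key) that satisfy category <= 3, p < alpha and expectation <= cutoff."""
    scoring = scoring or ScoringConfig()
    homology_keys = {(h.mirna_id, h.transcript_id, h.cleavage_position) for h in homology_sites}
    out = []
    for site in degradome_sites:
        key = (site.mirna_id, site.transcript_id, site.cleavage_position)
        if key not in homology_keys:
            continue
        if site.category > MAX_CATEGORY or site.p_value >= alpha or site.expectation > scoring.cutoff:
            continue
        out.append(site)
    return sorted(out, key=lambda s: (s.mirna_id, s.transcript_id, s.cleavage_position))


def detect_mite_in_target(
    region_seq: str,
    cleavage_offset: int,
    library: list[MiteElement],
    min_identity: float = 80.0,
    min_coverage: float = 0.8,
) -> str | None:
    """MITE insertion covering a cleavage location inside a gene region.

    ``cleavage_offset`` is 1-based within ``region_seq``.  A hit qualifies
    under the 80/80 rule (identity >= 80%, alignment >= 80% of the element
    length) and must span the cleavage offset; the best hit by identity is
    returned (ties: longer alignment, then smaller id)."""
    qualifying: list[tuple[float, int, str]] = []
    for element in library:
        for query in (element.sequence, revcomp(element.sequence)):
            for hit in find_local_hits(query, region_seq):
                if hit.identity < min_identity or hit.n_columns < min_coverage * element.length:
                    continue
                if not hit.t_start + 1 <= cleavage_offset <= hit.t_end:
                    continue
                qualifying.append((hit.identity, hit.n_columns, element.id))
    if not qualifying:
        return None
    # best by identity; ties: longer alignment, then smaller id
    return min(qualifying, key=lambda q: (-q[0], -q[1], q[2]))[2]


def label_region(model: TranscriptModel, cleavage_position: int) -> str:
    """five_prime_UTR / CDS / three_prime_UTR label of a transcript position."""
    return model.region_of(cleavage_position)


def annotate_sites(
    sites: list[TargetSite],
    models: dict[str, TranscriptModel],
    genome: dict[str, str],
    library: list[MiteElement],
) -> list[TargetSite]:
    """Label regions and detect MITEs at the cleavage location of each
    merged site, working on the unspliced gene region around the target
    transcript."""
    out = []
    for site in sites:
        model = models[site.transcript_id]
        region = label_region(model, site.cleavage_position)
        g_pos = model.to_genomic(site.cleavage_position)
        g_start = min(s for s, _ in model.exons)
        g_end = max(e for _, e in model.exons)
        region_seq = genome[model.chrom][g_start - 1 : g_end]
        mite = detect_mite_in_target(region_seq, g_pos - g_start + 1, library)
        out.append(
            TargetSite(site.mirna_id, site.transcript_id, site.cleavage_position,
                       site.expectation, site.category, site.p_value, region, mite)
        )
    return out


def profiles_from_table(df, transcripts: dict[str, str]) -> dict[str, DegradomeProfile]:
    """Degradome count table (transcript_id, position, count) to per-
    transcript profiles; positions beyond the transcript are rejected."""
    profiles = {}
    for tid, sub in df.groupby("transcript_id"):
        if tid not in transcripts:
            raise ValueError(f"degradome references unknown transcript {tid!r}")
        n = len(transcripts[tid])
        counts = np.zeros(n, dtype=int)
        if (sub["position"] < 1).any() or (sub["position"] > n).any():
            raise ValueError(f"degradome position outside transcript {tid!r}")
        np.add.at(counts, sub["position"].to_numpy() - 1, sub["count"].to_numpy())
        profiles[tid] = DegradomeProfile(tid, counts)
    return profiles
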