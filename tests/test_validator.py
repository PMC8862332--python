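"""The miRNA validation ladder: star geometry, duplex statistics and codes."""

import numpy as np
import pytest

from mitemir._types import ReadAlignment, SecondaryStructure, SrnaCluster
from mitemir.align import revcomp
from mitemir.fold import fold_rna
from mitemir.mirna_validator import (
    compute_star,
    duplex_stats,
    evaluate_locus,
)


def _hairpin_window(mature, loop="CACACAC", f5="AACCAACCAA", f3="AACCAACCAA", arm2=None):
    arm2 = arm2 if arm2 is not None else revcomp(mature)
    return f5 + mature + loop + arm2 + f3, len(f5)


class TestComputeStar:
    def test_perfect_stem_star_geometry(self):
        # manual geometry: mature on the 5' arm at offset f, star is the
        # partner region shifted by the 2-nt 3' overhang on each arm
        rng = np.random.default_rng(0)
        mature = "".join(rng.choice(list("ACGT"), 21))
        window, f = _hairpin_window(mature)
        structure = fold_rna(window)
        star = compute_star(structure, f, 21)
        assert star is not None
        s0, s1 = star
        loop_len = 7
        assert s0 == f + 21 + loop_len + 2
        assert s1 == f + 2 * 21 + loop_len + 1
        assert window[s0 : s1 - 1] == revcomp(mature)[2:]

    def test_unpaired_mature_fails(self):
        n = 40
        structure = SecondaryStructure("A" * n, "." * n, tuple([-1] * n))
        assert compute_star(structure, 5, 21) is None

    def test_palindromic_window_gives_distinct_arms(self):
        rng = np.random.default_rng(1)
        mature = "".join(rng.choice(list("ACGT"), 20))
        window, f = _hairpin_window(mature, loop="CAACA")
        structure = fold_rna(window)
        star = compute_star(structure, f, 20)
        assert star is not None
        s0, s1 = star
        assert s0 > f + 19 or s1 < f  # star never overlaps the mature


class TestDuplexStats:
    def test_perfect_duplex(self):
        rng = np.random.default_rng(2)
        mature = "".join(rng.choice(list("ACGT"), 21))
        window, f = _hairpin_window(mature)
        structure = fold_rna(window)
        star = compute_star(structure, f, 21)
        assert duplex_stats(structure, (f, f + 20), star) == (0, 0, 0)

    def test_interior_mismatch_counts_on_both_arms(self):
        # one engineered mismatch opposite the mature's middle: a 1-nt
        # bulge on each arm, one unpaired mature base
        rng = np.random.default_rng(3)
        mature = "".join(rng.choice(list("ACGT"), 21))
        arm2 = list(revcomp(mature))
        q = 10
        arm2[21 - 1 - q] = {"A": "C", "C": "A", "G": "A", "T": "C"}[mature[q]]
        window, f = _hairpin_window(mature, arm2="".join(arm2))
        structure = fold_rna(window)
        star = compute_star(structure, f, 21)
        n_bulges, n_bulged, mature_unpaired = duplex_stats(structure, (f, f + 20), star)
        assert (n_bulges, n_bulged, mature_unpaired) == (2, 2, 1)

    def test_hand_constructed_three_bulges(self):
        # dot-bracket with three 1-nt bulges on the 5' arm
        dots = "((((.((((.((((.((((....))))))))))))))))"
        seq = "GGGGAGGGGAGGGGAGGGGAAAACCCCCCCCCCCCCCCC"
        pairs = [-1] * len(dots)
        stack = []
        for i, ch in enumerate(dots):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                pairs[i], pairs[j] = j, i
        structure = SecondaryStructure(seq.replace("T", "U"), dots, tuple(pairs))
        n_bulges, n_bulged, _ = duplex_stats(structure, (0, 20), (21, 38))
        assert n_bulges == 3 and n_bulged == 3


def _locus_cluster(genome, chrom, mature_start, mature, star_start, star,
                   mature_n=50, star_n=5, extra=None):
    alignments = [
        ReadAlignment(mature, chrom, mature_start, "+", mature_n),
        ReadAlignment(star, chrom, star_start, "+", star_n),
    ]
    if extra:
        alignments += extra
    return SrnaCluster(chrom, min(a.start for a in alignments),
                       max(a.end for a in alignments), alignments)


@pytest.fixture(scope="module")
def designed_locus():
    """A clean planted hairpin on a random chromosome."""
    rng = np.random.default_rng(9)
    mature = "".join(rng.choice(list("ACGT"), 21))
    window, f = _hairpin_window(mature)
    flank_l = "".join(rng.choice(list("ACGT"), 300))
    flank_r = "".join(rng.choice(list("ACGT"), 300))
    genome = {"chrT": flank_l + window + flank_r}
    mature_start = len(flank_l) + f + 1
    star_start = len(flank_l) + f + 21 + 7 + 2 + 1
    star = genome["chrT"][star_start - 1 : star_start - 1 + 21]
    return genome, mature, mature_start, star, star_start


class TestLadderCodes:
    def test_no_reads_is_n1(self):
        cluster = SrnaCluster("chr1", 100, 200, [])
        assert evaluate_locus(cluster, {"chr1": "A" * 300}).result_code == "N1"

    def test_invalid_dicer_call_is_n2(self, designed_locus):
        genome, mature, mstart, star, sstart = designed_locus
        long_read = genome["chrT"][mstart - 1 : mstart + 27]
        cluster = _locus_cluster(genome, "chrT", mstart, long_read, sstart, star, mature_n=50, star_n=5)
        assert evaluate_locus(cluster, genome).result_code == "N2"

    def test_singleton_major_rna_is_n3(self, designed_locus):
        genome, mature, mstart, star, sstart = designed_locus
        cluster = SrnaCluster("chrT", mstart, mstart + 20,
                              [ReadAlignment(mature, "chrT", mstart, "+", 1)])
        assert evaluate_locus(cluster, genome).result_code == "N3"

    def test_locus_span_beyond_foldsize_is_n5(self, designed_locus):
        genome, mature, mstart, star, sstart = designed_locus
        far = ReadAlignment(genome["chrT"][mstart + 330 : mstart + 351], "chrT", mstart + 331, "+", 40)
        cluster = _locus_cluster(genome, "chrT", mstart, mature, sstart, star, extra=[far])
        assert evaluate_locus(cluster, genome, foldsize=300).result_code == "N5"

    def test_unstranded_locus_is_n6(self, designed_locus):
        genome, mature, mstart, star, sstart = designed_locus
        minus = ReadAlignment(revcomp(mature), "chrT", mstart, "-", 50)
        cluster = _locus_cluster(genome, "chrT", mstart, mature, sstart, star, mature_n=50, extra=[minus])
        assert evaluate_locus(cluster, genome).result_code == "N6"

    def test_clean_hairpin_with_star_is_y(self, designed_locus):
        genome, mature, mstart, star, sstart = designed_locus
        cluster = _locus_cluster(genome, "chrT", mstart, mature, sstart, star)
        locus = evaluate_locus(cluster, genome)
        assert locus.result_code == "Y"
        assert locus.mature_seq == mature
        assert locus.star_seq == star
        assert locus.precision >= 0.5

    def test_missing_star_read_is_n15(self, designed_locus):
        genome, mature, mstart, star, sstart = designed_locus
        # star replaced by a nearby non-star read: precision stays high but
        # the exact star was never sequenced
        near_star = genome["chrT"][sstart + 4 : sstart + 25]
        cluster = _locus_cluster(genome, "chrT", mstart, mature, sstart + 5, near_star,
                                 mature_n=50, star_n=2)
        locus = evaluate_locus(cluster, genome)
        assert locus.result_code in ("N14", "N15")

    def test_mature_count_monotonicity(self, designed_locus):
        # raising the mature read count never demotes a valid locus
        genome, mature, mstart, star, sstart = designed_locus
        for mature_n in (10, 50, 200, 1000):
            cluster = _locus_cluster(genome, "chrT", mstart, mature, sstart, star, mature_n=mature_n)
            assert evaluate_locus(cluster, genome).result_code == "Y"


class TestLadderOnCohort:
    def test_every_cluster_gets_exactly_one_code(self, pipeline_result):
        codes = [l.result_code for l in pipeline_result.loci]
        valid = {f"N{i}" for i in range(1, 16)} | {"Y"}
        assert all(c in valid for c in codes)
        assert len(codes) == len(pipeline_result.clusters)

    def test_planted_loci_recovered(self, pipeline_result):
        rec = pipeline_result.summary["recovery"]
        assert rec["mirna_recall"] >= 0.9
        assert rec["n_noise_y"] == 0
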