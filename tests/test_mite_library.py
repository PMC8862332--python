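"""MITE library clustering and genome annotation filter semantics."""

import random

import numpy as np
import pytest

from mitemir._types import MiteAnnotation, MiteElement
from mitemir.align import pairwise_identity, revcomp
from mitemir.fileio import gff_to_mite_annotations, read_gff3
from mitemir.mite_library import (
    annotate_genome,
    cluster_mites,
    cluster_representatives,
    deduplicate_annotations,
    write_mite_gff,
)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(rng, seq, k):
    """Exactly k substitutions at distinct positions."""
    arr = list(seq)
    for p in rng.choice(len(seq), size=k, replace=False):
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


class TestClusterMites:
    def test_identical_sequences_one_cluster(self):
        rng = np.random.default_rng(0)
        seq = _rand_seq(rng, 120)
        clusters = cluster_mites([MiteElement("a", seq), MiteElement("b", seq)])
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_curated_member_is_representative(self):
        rng = np.random.default_rng(1)
        seq = _rand_seq(rng, 200)
        variant = _mutate(rng, seq, 10)  # 95% identity
        clusters = cluster_mites(
            [MiteElement("novel_1", variant, "de_novo"), MiteElement("DTT_known", seq, "curated")]
        )
        assert len(clusters) == 1
        assert clusters[0].representative.id == "DTT_known"

    def test_dissimilar_sequences_stay_apart(self):
        rng = np.random.default_rng(2)
        elements = [MiteElement(f"e{i}", _rand_seq(rng, 150)) for i in range(4)]
        # the identity oracle confirms every pair is below the threshold
        for i in range(4):
            for j in range(i + 1, 4):
                assert pairwise_identity(elements[i].sequence, elements[j].sequence) < 0.8
        assert len(cluster_mites(elements)) == 4

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        base = _rand_seq(rng, 180)
        elements = [MiteElement("a", base), MiteElement("b", _mutate(rng, base, 9)),
                    MiteElement("c", _rand_seq(rng, 180)), MiteElement("DTT_x", _mutate(rng, base, 5), "curated")]
        ref = {c.representative.id: sorted(m.id for m in c.members) for c in cluster_mites(elements)}
        shuffled = elements[::-1]
        random.Random(0).shuffle(shuffled)
        assert {c.representative.id: sorted(m.id for m in c.members) for c in cluster_mites(shuffled)} == ref

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_mites([])


@pytest.fixture(scope="module")
def planted_genome():
    """A genome with planted copies exercising every annotation filter."""
    rng = np.random.default_rng(7)
    element = MiteElement("MITE_A", _rand_seq(rng, 200))
    pieces = [_rand_seq(rng, 1000)]
    layout = {}

    def plant(seq, name):
        layout[name] = sum(len(p) for p in pieces)
        pieces.append(seq)
        pieces.append(_rand_seq(rng, 700))

    plant(element.sequence, "exact")                      # passes everything
    plant(element.sequence[:45], "short45")               # span < 50 -> dropped
    plant(_mutate(rng, element.sequence, 60), "diverged") # 70% identity -> dropped
    plant(element.sequence[:130], "partial65")            # 65% coverage -> dropped
    plant(revcomp(element.sequence), "minus")             # found on - strand
    return element, "".join(pieces), layout


class TestAnnotateGenome:
    def test_exact_copy_annotated(self, planted_genome):
        element, genome, layout = planted_genome
        annotations = annotate_genome({"chr1": genome}, [element])
        exact = [a for a in annotations if a.start == layout["exact"] + 1]
        assert len(exact) == 1
        assert exact[0].identity == 100.0 and exact[0].align_length == 200
        assert exact[0].end == layout["exact"] + 200

    def test_short_low_identity_and_partial_hits_filtered(self, planted_genome):
        element, genome, layout = planted_genome
        annotations = annotate_genome({"chr1": genome}, [element])
        starts = {a.start for a in annotations}
        for name in ("short45", "diverged", "partial65"):
            assert not any(abs(s - (layout[name] + 1)) < 30 for s in starts), name

    def test_minus_strand_copy_found(self, planted_genome):
        element, genome, layout = planted_genome
        annotations = annotate_genome({"chr1": genome}, [element])
        minus = [a for a in annotations if a.strand == "-"]
        assert len(minus) == 1 and minus[0].start == layout["minus"] + 1

    def test_empty_genome_is_empty_result(self):
        assert annotate_genome({"chr1": ""}, [MiteElement("x", "ACGT" * 30)]) == []

    def test_oversized_span_filtered(self):
        rng = np.random.default_rng(11)
        element = MiteElement("big", _rand_seq(rng, 1400))
        genome = _rand_seq(rng, 500) + element.sequence + _rand_seq(rng, 500)
        # a full-length 1400-nt copy violates the 1100-nt span ceiling
        assert annotate_genome({"chr1": genome}, [element]) == []


class TestDeduplication:
    def test_nearby_hits_collapse_to_best(self):
        a1 = MiteAnnotation("chr1", 1000, 1400, "+", "m1", 99.0, 400)
        a2 = MiteAnnotation("chr1", 1002, 1401, "+", "m2", 95.0, 398)
        kept = deduplicate_annotations([a1, a2])
        assert kept == [a1]

    def test_distance_five_is_distinct(self):
        a1 = MiteAnnotation("chr1", 1000, 1400, "+", "m1", 99.0, 400)
        a2 = MiteAnnotation("chr1", 1005, 1405, "+", "m2", 95.0, 398)
        assert len(deduplicate_annotations([a1, a2])) == 2

    def test_equal_identity_breaks_on_id(self):
        a1 = MiteAnnotation("chr1", 1000, 1400, "+", "m_b", 99.0, 400)
        a2 = MiteAnnotation("chr1", 1001, 1401, "+", "m_a", 99.0, 400)
        assert deduplicate_annotations([a1, a2])[0].mite_id == "m_a"


class TestGffOutput:
    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "empty.gff3"
        write_mite_gff([], path)
        assert path.read_text() == "##gff-version 3\n"

    def test_round_trip(self, tmp_path):
        ann = MiteAnnotation("chr2", 10, 209, "-", "MITE_X", 97.5, 198)
        path = tmp_path / "one.gff3"
        write_mite_gff([ann], path)
        assert gff_to_mite_annotations(read_gff3(path)) == [ann]

    def test_sorted_by_chrom_then_start(self, tmp_path):
        anns = [
            MiteAnnotation("chr2", 50, 260, "+", "a", 90.0, 200),
            MiteAnnotation("chr1", 900, 1100, "+", "b", 90.0, 200),
            MiteAnnotation("chr1", 5, 210, "+", "c", 90.0, 200),
        ]
        path = tmp_path / "three.gff3"
        write_mite_gff(anns, path)
        got = [(f.chrom, f.start) for f in read_gff3(path)]
        assert got == sorted(got)


class TestRecoveryOnSyntheticGenome(object):
    def test_planted_copies_recovered_with_full_precision(self, default_sim, pipeline_result):
        truth = default_sim.truth
        annotations = pipeline_result.mite_annotations
        eligible = [m for m in truth.planted_mites if 50 <= m.end - m.start + 1 <= 1100]
        found = sum(
            any(a.chrom == m.chrom and abs(a.start - m.start) < 25 and abs(a.end - m.end) < 25 for a in annotations)
            for m in eligible
        )
        assert found / len(eligible) >= 0.95
        for a in annotations:
            assert any(
                a.chrom == m.chrom and a.start <= m.end and m.start <= a.end for m in truth.planted_mites
            ), f"annotation {a} overlaps no planted copy"
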