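"""Target prediction: expectation score, degradome categories, permutation
p-values, evidence merging and MITE-in-target detection."""

import numpy as np
import pytest
from scipy import stats

from mitemir._types import DegradomeProfile, MiteElement, TargetSite
from mitemir.align import revcomp
from mitemir.fileio import TranscriptModel
from mitemir.targets import (
    CandidateSite,
    ScoringConfig,
    cleavage_category,
    cleavage_pvalue,
    degradome_evidence_multilibrary,
    detect_mite_in_target,
    expectation_score,
    label_region,
    merge_evidence,
    scan_transcripts,
)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestExpectationScore:
    def test_perfect_site_scores_zero(self):
        rng = np.random.default_rng(0)
        mirna = _rand_seq(rng, 21)
        assert expectation_score(mirna, revcomp(mirna)) == 0.0

    def test_gu_wobble_outside_seed(self):
        # G:U at miRNA position 18 (outside seed 2-13): penalty 0.5 x 1.0
        mirna = "A" * 21
        site = list(revcomp(mirna))  # all T
        # miRNA position 18 pairs site index 21-18 = 3 (0-based, 5'->3')
        mirna = mirna[:17] + "G" + mirna[18:]
        site[3] = "T"  # G:U wobble (G pairs T read as U)
        assert expectation_score(mirna, "".join(site)) == pytest.approx(0.5)

    def test_mismatch_in_seed_multiplied(self):
        # a mismatch at miRNA position 5 (seed region): 1.0 x 1.5
        mirna = "A" * 21
        site = list(revcomp(mirna))
        site[21 - 5] = "C"  # A opposite C: mismatch
        assert expectation_score(mirna, "".join(site)) == pytest.approx(1.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            expectation_score("", "ACGT")

    def test_gap_allows_better_score_than_forced_mismatches(self):
        rng = np.random.default_rng(1)
        mirna = _rand_seq(rng, 21)
        site = revcomp(mirna)
        bulged = site[:10] + "A" + site[10:]  # 22-nt site with 1-nt bulge
        score = expectation_score(mirna, bulged)
        assert score <= 2.0 * 1.5 + 0.01  # at most one (seed-weighted) gap open


class TestScanTranscripts:
    def test_exact_site_found_with_conventional_cleavage_position(self):
        rng = np.random.default_rng(2)
        mirna = _rand_seq(rng, 21)
        prefix = _rand_seq(rng, 400)
        tx = prefix + revcomp(mirna) + _rand_seq(rng, 300)
        sites = scan_transcripts("m", mirna, {"t1": tx})
        exact = [s for s in sites if s.expectation == 0.0]
        assert len(exact) == 1
        # cleavage opposite miRNA position 10: site starts at 401 (1-based)
        assert exact[0].cleavage_position == 401 + 21 - 10

    def test_all_reported_sites_verified_by_scoring_oracle(self):
        rng = np.random.default_rng(3)
        mirna = _rand_seq(rng, 21)
        tx = _rand_seq(rng, 1500)
        scoring = ScoringConfig()
        for site in scan_transcripts("m", mirna, {"t": tx}, scoring):
            w = site.cleavage_position - 21 + 9
            window = tx[w : w + 21]
            assert expectation_score(mirna, window, scoring) <= scoring.cutoff + 1e-9

    def test_empty_transcript_set(self):
        assert scan_transcripts("m", "ACGT" * 5 + "A", {}) == []


class TestCleavageCategory:
    def test_unique_maximum_is_zero(self):
        counts = np.array([3, 1, 0, 50, 2, 1])
        assert cleavage_category(DegradomeProfile("t", counts), 4) == 0

    def test_tied_maximum_is_one(self):
        counts = np.array([50, 1, 0, 50, 2, 1])
        assert cleavage_category(DegradomeProfile("t", counts), 4) == 1

    def test_single_read_is_four(self):
        counts = np.array([5, 1, 0, 1, 9])
        assert cleavage_category(DegradomeProfile("t", counts), 2) == 4

    def test_above_median_below_max_is_two(self):
        counts = np.array([1, 1, 1, 9, 5, 1, 1])
        assert cleavage_category(DegradomeProfile("t", counts), 5) == 2

    def test_at_or_below_median_is_three(self):
        counts = np.array([9, 5, 5, 5, 0, 2])
        assert cleavage_category(DegradomeProfile("t", counts), 2) == 3

    def test_zero_count_site_dropped(self):
        counts = np.array([9, 0, 5])
        assert cleavage_category(DegradomeProfile("t", counts), 2) is None

    def test_category_is_total_and_exclusive_over_small_vectors(self):
        # every position of every count vector of length <= 6 with entries
        # in {0..3} receives exactly one category, matching an independent
        # rank-based re-derivation
        from itertools import product

        for n in range(1, 7):
            for vec in product(range(4), repeat=n):
                counts = np.array(vec)
                profile = DegradomeProfile("t", counts)
                for pos in range(1, n + 1):
                    got = cleavage_category(profile, pos)
                    r = vec[pos - 1]
                    if r == 0:
                        expected = None
                    elif r == 1:
                        expected = 4
                    else:
                        positive = sorted(v for v in vec if v > 0)
                        med = float(np.median(positive))
                        mx = max(vec)
                        if r == mx:
                            expected = 0 if vec.count(mx) == 1 else 1
                        elif r > med:
                            expected = 2
                        else:
                            expected = 3
                    assert got == expected, (vec, pos)


class TestCleavagePvalue:
    def _spiked_profile(self, n, pos, spike=30):
        counts = np.zeros(n, dtype=int)
        counts[pos - 1] = spike
        return DegradomeProfile("t", counts)

    def test_perfect_site_on_long_transcript_is_significant(self):
        # Monte-Carlo property: expectation 0 against a random 2-kb
        # transcript is essentially never matched by shuffled miRNAs
        rng = np.random.default_rng(4)
        hits = 0
        for rep in range(50):
            mirna = _rand_seq(rng, 21)
            tx = _rand_seq(rng, 2000)
            pos = 1000
            w = pos - 21 + 9
            tx = tx[:w] + revcomp(mirna) + tx[w + 21 :]
            profile = self._spiked_profile(len(tx), pos)
            p = cleavage_pvalue(mirna, tx, profile, pos, 0, n_perm=200, seed=rep)
            hits += p <= 0.05
        assert hits / 50 >= 0.95

    def test_degenerate_single_base_mirna_gives_p_one(self):
        mirna = "A" * 21
        tx = "C" * 200
        profile = self._spiked_profile(200, 100)
        assert cleavage_pvalue(mirna, tx, profile, 100, 0, n_perm=200, seed=0) == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        mirna = _rand_seq(rng, 21)
        tx = _rand_seq(rng, 800)
        profile = self._spiked_profile(800, 300)
        p1 = cleavage_pvalue(mirna, tx, profile, 300, 0, n_perm=300, seed=11)
        p2 = cleavage_pvalue(mirna, tx, profile, 300, 0, n_perm=300, seed=11)
        assert p1 == p2

    def test_null_pvalues_are_uniform(self):
        # random miRNA vs random transcript with a forced site: the
        # permutation p-value follows U(0,1) (KS test at alpha 0.01)
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(500):
            mirna = _rand_seq(rng, 21)
            tx = _rand_seq(rng, 600)
            pos = int(rng.integers(30, 560))
            profile = self._spiked_profile(600, pos)
            category = cleavage_category(profile, pos)
            p = cleavage_pvalue(mirna, tx, profile, pos, category,
                                n_perm=200, seed=int(rng.integers(2**31)))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMultiLibraryEvidence:
    def test_best_supported_record_wins_across_libraries(self):
        rng = np.random.default_rng(8)
        mirna = _rand_seq(rng, 21)
        pos = 500
        w = pos - 21 + 9
        tx = _rand_seq(rng, 1000)
        tx = tx[:w] + revcomp(mirna) + tx[w + 21 :]
        transcripts = {"t1": tx}
        spike = np.zeros(1000, dtype=int)
        spike[pos - 1] = 40  # unique maximum: category 0
        weak = np.full(1000, 3, dtype=int)  # site tied with everything: category 1
        profiles = {
            "libA": {"t1": DegradomeProfile("t1", weak)},
            "libB": {"t1": DegradomeProfile("t1", spike)},
        }
        candidates = scan_transcripts("m", mirna, transcripts)
        sites = degradome_evidence_multilibrary(
            candidates, transcripts, profiles, {"m": mirna}, n_perm=200, seed=0
        )
        site = next(s for s in sites if s.cleavage_position == pos)
        assert site.category == 0  # the spiked library supports it best
        assert site.p_value < 0.05


class TestMergeEvidence:
    def _site(self, category=1, p=0.008, expectation=1.0):
        return TargetSite("m1", "t1", 500, expectation, category, p)

    def _homology(self):
        return [CandidateSite("m1", "t1", 500, 1.0)]

    def test_supported_by_both_kept(self):
        assert merge_evidence([self._site()], self._homology()) == [self._site()]

    def test_degradome_only_dropped(self):
        assert merge_evidence([self._site()], []) == []

    def test_category_four_dropped(self):
        assert merge_evidence([self._site(category=4)], self._homology()) == []

    def test_weak_pvalue_dropped(self):
        assert merge_evidence([self._site(p=0.07)], self._homology()) == []

    def test_expectation_above_cutoff_dropped(self):
        assert merge_evidence([self._site(expectation=6.0)], self._homology()) == []


class TestMiteInTarget:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.element = MiteElement("MITE_9", _rand_seq(rng, 160))
        self.flank = _rand_seq(rng, 300)
        self.flank2 = _rand_seq(rng, 300)

    def test_copy_spanning_cleavage_site_reported(self):
        region = self.flank + self.element.sequence + self.flank2
        cleavage = 300 + 80
        assert detect_mite_in_target(region, cleavage, [self.element]) == "MITE_9"

    def test_copy_not_covering_site_ignored(self):
        region = self.flank + self.element.sequence + self.flank2
        cleavage = 300 + 160 + 20  # 20 nt downstream of the copy
        assert detect_mite_in_target(region, cleavage, [self.element]) is None

    def test_no_mite_near_gene(self):
        assert detect_mite_in_target(self.flank, 150, [self.element]) is None


class TestLabelRegion:
    def _model(self):
        return TranscriptModel("t1", "g1", "chr1", "+", [(1001, 1500), (1901, 2600)],
                               utr5_len=200, cds_len=700, utr3_len=300)

    def test_positions_map_to_segments(self):
        model = self._model()
        assert label_region(model, 1) == "five_prime_UTR"
        assert label_region(model, 200) == "five_prime_UTR"
        assert label_region(model, 201) == "CDS"
        assert label_region(model, 900) == "CDS"
        assert label_region(model, 901) == "three_prime_UTR"
        assert label_region(model, 1200) == "three_prime_UTR"

    def test_position_outside_transcript_rejected(self):
        with pytest.raises(ValueError):
            label_region(self._model(), 1300)


class TestTargetRecovery:
    def test_planted_sites_survive_the_merged_filter(self, pipeline_result):
        rec = pipeline_result.summary["recovery"]
        assert rec["target_recall"] >= 0.9
        assert rec["n_mite_in_target_concordant"] == rec["n_recovered_targets"]

    def test_every_mite_flagged_target_reports_an_element(self, pipeline_result):
        truth = pipeline_result.sim.truth
        flagged = {
            (t.transcript_id, t.cleavage_position)
            for t in truth.planted_targets if t.has_mite_in_target
        }
        for site in pipeline_result.merged_sites:
            if (site.transcript_id, site.cleavage_position) in flagged:
                assert site.mite_in_target is not None
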