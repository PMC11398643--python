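"""ESB rebalancing: variant enumeration, screens, genome search, pipeline."""
import numpy as np
import pytest

from conftest import brute_force_sites
from crisprmca.errors import DatasetFormatError, InvalidAlphabetError
from crisprmca.esb import (
    EsbConfig,
    OffTargetCandidate,
    efficiency_screen,
    enumerate_single_substitutions,
    esb_rebalance,
    find_candidate_sites,
    specificity_score,
)
from crisprmca.pairs import DNA_BASES, GuideTargetPair, reverse_complement
from crisprmca.scoring import GUIDE_LENGTH, ScoreTable, crisot_score
from crisprmca.stats import ImbalanceReport
from crisprmca.synthetic import generate_toy_genome

GUIDE = "ACGTACGTACGTACGTACGT"


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestEnumerateVariants:
    def test_sixty_distinct_hamming_one(self):
        variants = enumerate_single_substitutions(GUIDE)
        assert len(variants) == 60
        seqs = {v.sequence for v in variants}
        assert len(seqs) == 60 and GUIDE not in seqs
        assert all(_hamming(GUIDE, s) == 1 for s in seqs)

    def test_no_self_substitution(self):
        for v in enumerate_single_substitutions("A" * 20):
            assert v.new_base != "A"
            assert v.sequence[v.position - 1] == v.new_base

    def test_deterministic_ordering(self):
        a = [v.sequence for v in enumerate_single_substitutions(GUIDE)]
        b = [v.sequence for v in enumerate_single_substitutions(GUIDE)]
        assert a == b
        assert a[0] == "C" + GUIDE[1:]  # position 1, base C (A is the parent base)

    @pytest.mark.parametrize("bad", ["ACGT", "A" * 19, "A" * 19 + "_", "A" * 21])
    def test_invalid_guides_rejected(self, bad):
        with pytest.raises(InvalidAlphabetError):
            enumerate_single_substitutions(bad)


class TestEfficiencyScreen:
    def _pair(self, guide20, target20):
        return GuideTargetPair(guide20 + "AGG", target20 + "AGG", label=1)

    def test_zero_table_passes_nothing(self, zero_table):
        variants = enumerate_single_substitutions(GUIDE)
        passing = efficiency_screen(self._pair(GUIDE, GUIDE), variants, zero_table)
        assert passing == []
        assert all(v.efficiency == 0.5 for v in variants)

    def test_single_favorable_cell_identified_by_enumeration(self):
        # one cell (position 5, guide C, target A) earns +delta; exactly the
        # variant writing C at position 5 against target A should pass
        v = np.zeros((GUIDE_LENGTH, 4, 4))
        v[4, DNA_BASES.index("C"), DNA_BASES.index("A")] = 0.2
        table = ScoreTable(v=v, a=1.0, b=0.0)
        target = "A" * 20
        parent = "A" * 20  # parent scores 0 against the all-A target
        variants = enumerate_single_substitutions(parent)
        passing = efficiency_screen(self._pair(parent, target), variants, table)
        expected = {s.sequence for s in variants if s.position == 5 and s.new_base == "C"}
        assert {p.sequence for p in passing} == expected
        # oracle: recompute all 60 scores independently
        parent_score = crisot_score(parent, target, table)
        brute = {
            s.sequence
            for s in variants
            if crisot_score(s.sequence, target, table) > parent_score
        }
        assert {p.sequence for p in passing} == brute

    def test_saturated_parent_blocks_all(self):
        table = ScoreTable(v=np.full((GUIDE_LENGTH, 4, 4), 1.0), a=1.0, b=0.0)
        variants = enumerate_single_substitutions(GUIDE)
        assert efficiency_screen(self._pair(GUIDE, GUIDE), variants, table) == []


class TestFindCandidateSites:
    def test_planted_exact_site(self):
        genome, truth = generate_toy_genome(1200, [(GUIDE, 0, "+")], seed=3)
        hits = find_candidate_sites(GUIDE, genome, max_mm=0)
        planted = truth.iloc[0]
        assert any(
            c.start == planted.start and c.strand == "+" and c.n_mismatch == 0
            for c in hits
        )

    def test_pam_mismatch_rejected(self):
        genome = {"chr1": "T" * 50 + GUIDE + "ATT" + "T" * 50}
        assert find_candidate_sites(GUIDE, genome, max_mm=1) == []

    def test_minus_strand_coordinates(self):
        site = GUIDE + "TGG"
        genome = {"chr1": "T" * 40 + reverse_complement(site) + "T" * 40}
        hits = find_candidate_sites(GUIDE, genome, max_mm=0)
        assert len(hits) == 1
        c = hits[0]
        assert c.strand == "-" and c.start == 40 and c.site_seq == site

    def test_ambiguous_characters_never_match(self):
        # N in the protospacer counts as a mismatch; N in GG or the N slot
        # disqualifies the window
        base = "T" * 30
        g_in_proto = base + GUIDE[:10] + "N" + GUIDE[11:] + "AGG" + base
        assert find_candidate_sites(GUIDE, {"c": g_in_proto}, max_mm=0) == []
        assert len(find_candidate_sites(GUIDE, {"c": g_in_proto}, max_mm=1)) == 1
        g_in_gg = base + GUIDE + "ANG" + base
        assert find_candidate_sites(GUIDE, {"c": g_in_gg}, max_mm=1) == []
        g_in_nslot = base + GUIDE + "NGG" + base
        assert find_candidate_sites(GUIDE, {"c": g_in_nslot}, max_mm=1) == []

    def test_empty_and_short_genomes(self):
        assert find_candidate_sites(GUIDE, {"c": ""}, max_mm=2) == []
        assert find_candidate_sites(GUIDE, {"c": "ACGT"}, max_mm=2) == []

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_brute_force_equivalence_small(self, max_mm, rng):
        for trial in range(3):
            guide = "".join(rng.choice(list(DNA_BASES), size=20))
            genome, _ = generate_toy_genome(
                2000, [(guide, mm, s) for mm, s in [(0, "+"), (1, "-"), (2, "+")]],
                seed=100 + trial,
            )
            hits = {
                (c.chrom, c.start, c.strand, c.n_mismatch, c.site_seq)
                for c in find_candidate_sites(guide, genome, max_mm)
            }
            assert hits == brute_force_sites(guide, genome, max_mm)


class TestSpecificityScore:
    def _candidate(self, proto, start=0):
        return OffTargetCandidate(proto + "AGG", "chr1", start, "+", 1)

    def test_no_candidates_perfectly_specific(self, score_table):
        assert specificity_score(GUIDE, GUIDE, [], score_table) == 1.0

    def test_on_target_locus_excluded(self, score_table):
        assert specificity_score(GUIDE, GUIDE, [self._candidate(GUIDE)], score_table) == 1.0

    def test_equal_scores_give_half(self, zero_table):
        # constant table: every 20-mer scores 0.5, so one off-site halves it
        off = self._candidate("T" * 20)
        assert specificity_score(GUIDE, GUIDE, [off], zero_table) == pytest.approx(0.5)

    def test_three_sites_match_hand_sum(self, score_table):
        protos = ["T" * 20, "C" * 20, GUIDE[:10] + "T" * 10]
        cands = [self._candidate(p, i * 30) for i, p in enumerate(protos)]
        s_on = crisot_score(GUIDE, GUIDE, score_table)
        s_off = sum(crisot_score(GUIDE, p, score_table) for p in protos)
        expected = s_on / (s_on + s_off)
        assert specificity_score(GUIDE, GUIDE, cands, score_table) == pytest.approx(expected)

    def test_zero_on_target_with_candidates(self):
        v = np.zeros((GUIDE_LENGTH, 4, 4))
        v[0, 1, 2] = 1.0  # only C->G at position 1 scores
        table = ScoreTable(v=v, a=1.0, b=0.0)
        off = self._candidate("G" + "A" * 19)
        assert specificity_score("C" + "A" * 19, "A" * 20, [off], table) == 0.0


def _make_training_data(rng, n_guides=3, negs_per_guide=40):
    """Small labeled dataset: positives are near-matched pairs."""
    pairs = []
    guides = []
    for gi in range(n_guides):
        g20 = "".join(rng.choice(list(DNA_BASES), size=20))
        guides.append(g20)
        pam = "TGG"
        t = list(g20)
        t[1] = [b for b in DNA_BASES if b != t[1]][0]
        pairs.append(GuideTargetPair(g20 + pam, "".join(t) + pam, 1, f"pos{gi}"))
        for nj in range(negs_per_guide):
            t = list(g20)
            for pos in rng.choice(20, size=4, replace=False):
                t[pos] = rng.choice([b for b in DNA_BASES if b != t[pos]])
            pairs.append(GuideTargetPair(g20 + pam, "".join(t) + pam, 0, f"neg{gi}:{nj}"))
    return pairs, guides


@pytest.fixture()
def esb_setting(rng, score_table):
    train, guides = _make_training_data(rng)
    planted = []
    for g in guides:
        planted += [(g, 0, "+"), (g, 1, "+"), (g, 1, "-")]
    genome, _ = generate_toy_genome(2500, planted, seed=5)
    test, _ = _make_training_data(np.random.default_rng(999), n_guides=1, negs_per_guide=5)
    return train, test, genome


class TestEsbRebalance:
    def test_degenerate_table_is_noop(self, esb_setting, zero_table):
        train, test, genome = esb_setting
        result = esb_rebalance(train, test, genome, zero_table)
        assert [(p.guide, p.target, p.label) for p in result.train] == [
            (p.guide, p.target, p.label) for p in train
        ]
        assert result.n_new_positives == 0

    def test_augmentation_properties(self, esb_setting, score_table):
        train, test, genome = esb_setting
        result = esb_rebalance(train, test, genome, score_table)
        before = ImbalanceReport.from_pairs(train)
        after = ImbalanceReport.from_pairs(result.train)
        # originals all preserved, negatives untouched
        originals = {(p.guide, p.target, p.label) for p in train}
        augmented = {(p.guide, p.target, p.label) for p in result.train}
        assert originals <= augmented
        assert after.n_neg == before.n_neg
        if result.n_new_positives:
            assert after.n_pos > before.n_pos
            assert after.ir < before.ir
            # exact arithmetic identity for the post-rebalancing ratio
            assert after.ir == pytest.approx(
                before.n_neg / (before.n_pos + result.n_new_positives)
            )
        # every added record is a Hamming-1 mutant paired with its parent target
        added = augmented - originals
        parents = {p.guide: p for p in train if p.label == 1}
        for guide, target, label in added:
            assert label == 1
            parent = next(
                p for p in train if p.label == 1 and p.target == target
            )
            assert _hamming(parent.guide[:20], guide[:20]) == 1
            assert guide[20:] == parent.guide[20:]

    def test_accepted_variants_beat_parent_on_both_screens(
        self, esb_setting, score_table
    ):
        train, test, genome = esb_setting
        result = esb_rebalance(train, test, genome, score_table)
        assert result.n_new_positives > 0  # the favorable setting yields variants
        originals = {(p.guide, p.target) for p in train}
        for rec in result.train:
            if (rec.guide, rec.target) in originals:
                continue
            parent = next(
                p for p in train if p.label == 1 and p.target == rec.target
            )
            g_parent, g_var = parent.guide[:20], rec.guide[:20]
            t20 = parent.target[:20]
            assert crisot_score(g_var, t20, score_table) > crisot_score(
                g_parent, t20, score_table
            )
            spec_var = specificity_score(
                g_var, g_var, find_candidate_sites(g_var, genome, 1), score_table
            )
            spec_parent = specificity_score(
                g_parent, g_parent, find_candidate_sites(g_parent, genome, 1), score_table
            )
            assert spec_var > spec_parent

    def test_leakage_rule_removes_test_guides(self, esb_setting, score_table):
        train, _, genome = esb_setting
        # find a variant that would be accepted, then plant it as a test guide
        free = esb_rebalance(train, [], genome, score_table)
        added = [
            p for p in free.train
            if (p.guide, p.target) not in {(q.guide, q.target) for q in train}
        ]
        assert added, "setting must produce at least one accepted variant"
        leak = added[0]
        test = [GuideTargetPair(leak.guide, leak.guide, 0, "planted-test")]
        result = esb_rebalance(train, test, genome, score_table)
        assert all(p.guide != leak.guide or p.target != leak.target for p in result.train)

    def test_empty_positive_set_warns(self, esb_setting, zero_table):
        train, test, genome = esb_setting
        negatives = [p for p in train if p.label == 0]
        with pytest.warns(UserWarning, match="no positive records"):
            result = esb_rebalance(negatives, test, genome, zero_table)
        assert len(result.train) == len(negatives)

    def test_gapped_positive_rejected(self, esb_setting, zero_table):
        train, test, genome = esb_setting
        gapped = GuideTargetPair("_" + "A" * 23, "G" + "A" * 23, 1, "bulge")
        with pytest.raises(DatasetFormatError):
            esb_rebalance(train + [gapped], test, genome, zero_table)
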