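import pytest

from staligner.aligner import (
    SearchParams,
    align_read,
    inexact_search,
    mapping_quality,
    replay_script,
)
from staligner.fm_index import Sequence, build_fm_index, revcomp
from staligner.io import IndexBundle
from staligner.pruning import (
    FrequentPattern,
    build_ac_automaton,
    calculate_d_basic,
    calculate_d_dcdc,
)
from staligner.suffix_tarray import SuffixTarray

from conftest import random_dna
from oracles import brute_positions, substitution_variants


def positions_of(fm, hits):
    return {p for h in hits for p in fm.locate(h.interval)}


def make_bundle(text, **kwargs):
    return IndexBundle.build([Sequence("ref", text)], **kwargs)


def plant_subs(rng, window, k):
    out = list(window)
    for i in rng.sample(range(len(window)), k):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestInexactSearch:
    def test_z0_equals_exact_search(self, rng):
        x = random_dna(rng, 500)
        fm = build_fm_index(x)
        rev = build_fm_index(x[::-1])
        for _ in range(20):
            i = rng.randrange(len(x) - 20)
            w = x[i : i + 20]
            hits = inexact_search(w, fm, calculate_d_basic(w, rev), SearchParams(z=0))
            assert positions_of(fm, hits) == brute_positions(x, w)
            assert all(h.diff == 0 and h.script == () for h in hits)

    def test_z0_random_read_finds_nothing(self, rng):
        x = random_dna(rng, 100)
        w = "ACGTACGTACGTACGTACGTACGTACGT"  # 28-mer almost surely absent
        if w in x:
            pytest.skip("coincidental containment")
        fm = build_fm_index(x)
        assert inexact_search(w, fm, None, SearchParams(z=0)) == []

    def test_branch_pruned_when_bound_exceeds_budget(self):
        # Direct unit check of the prune rule: with z = 1 and D[i] = 2 at
        # every remaining position, even a read one substitution away from
        # the reference must come back empty.
        x = "ACGTTGCAACGTTGCA"
        fm = build_fm_index(x)
        w = "ACGTAGCA"  # one substitution from x[0:8]
        from staligner.pruning import DArray

        blocking = DArray(tuple([2] * len(w)))
        assert inexact_search(w, fm, blocking, SearchParams(z=1)) == []
        rev = build_fm_index(x[::-1])
        honest = calculate_d_basic(w, rev)
        assert positions_of(fm, inexact_search(w, fm, honest, SearchParams(z=1)))

    @pytest.mark.parametrize("z", [1, 2])
    def test_completeness_against_variant_enumeration(self, rng, z):
        x = random_dna(rng, 500)
        fm = build_fm_index(x)
        rev = build_fm_index(x[::-1])
        params = SearchParams(z=z)
        for _ in range(5):
            start = rng.randrange(len(x) - 18)
            w = plant_subs(rng, x[start : start + 18], z)
            got = positions_of(fm, inexact_search(w, fm, calculate_d_basic(w, rev), params))
            expected = set()
            for variant in substitution_variants(w, z):
                expected |= brute_positions(x, variant)
            assert expected <= got
            assert start in got

    def test_pruning_on_off_identity_when_all_columns_charged(self, rng):
        # With max_gap_extensions = 0 every column costs 1, the same metric
        # the D-array bounds, so pruning cannot change the hit set.
        x = random_dna(rng, 300)
        fm = build_fm_index(x)
        rev = build_fm_index(x[::-1])
        params = SearchParams(z=2, max_gap_extensions=0)
        for _ in range(8):
            start = rng.randrange(len(x) - 16)
            w = plant_subs(rng, x[start : start + 16], rng.randint(0, 2))
            d = calculate_d_basic(w, rev)
            pruned = {
                (h.interval, h.diff) for h in inexact_search(w, fm, d, params)
            }
            free = {
                (h.interval, h.diff) for h in inexact_search(w, fm, None, params)
            }
            assert pruned == free

    def test_sta_and_fm_give_identical_results(self, rng):
        x = random_dna(rng, 400)
        fm = build_fm_index(x)
        rev = build_fm_index(x[::-1])
        sta = SuffixTarray.build(fm, rev, epsilon=2, max_depth=6)
        params = SearchParams(z=2)
        for _ in range(6):
            start = rng.randrange(len(x) - 15)
            w = plant_subs(rng, x[start : start + 15], rng.randint(0, 2))
            d = calculate_d_basic(w, rev)
            via_fm = {(h.interval, h.diff) for h in inexact_search(w, fm, d, params)}
            via_sta = {(h.interval, h.diff) for h in inexact_search(w, sta, d, params)}
            assert via_fm == via_sta

    def test_every_script_replays_to_a_reference_window(self, rng):
        x = random_dna(rng, 400)
        fm = build_fm_index(x)
        rev = build_fm_index(x[::-1])
        params = SearchParams(z=3, max_gap_extensions=2)
        for _ in range(5):
            start = rng.randrange(len(x) - 20)
            w = plant_subs(rng, x[start : start + 20], rng.randint(0, 2))
            for h in inexact_search(w, fm, calculate_d_basic(w, rev), params):
                window = replay_script(w, h.script)
                for pos in fm.locate(h.interval):
                    assert x[pos : pos + len(window)] == window

    def test_gap_extension_costs_nothing_within_cap(self):
        # Read skips 3 reference bases: one open plus two free extensions.
        left, gap, right = "TTACGTCA", "GGG", "CATGACAT"
        x = "ACCA" + left + gap + right + "TGTC"
        w = left + right
        fm = build_fm_index(x)
        hits = inexact_search(w, fm, None, SearchParams(z=1, max_gap_extensions=2))
        assert 4 in positions_of(fm, hits)
        hits_short = inexact_search(w, fm, None, SearchParams(z=1, max_gap_extensions=1))
        assert 4 not in positions_of(fm, hits_short)


FIG5_X = (
    "AACTTGTTGCTAAAGGGGACAATTACATTAACATACAGGTCAACACGGCCCAGTTAAGATGTGAATCGAAC"
    "ATACACGTCAGCACCTTAAGGG"
)
FIG5_W = "GCTAAAGACAATTACATAACATACACGTCAGCAC"
FIG5_PATTERN = "AAAGAC"
FIG5_TARGET_POS = 8  # window: 2 substitutions + a 1-col and a 3-col deletion
FIG5_CRITICAL = 24


class TestCostMetricDivergenceRegression:
    """The documented divergence: the search charges gap extensions 0 while
    both D-arrays charge them 1, so the tighter pattern bound can prune a
    within-budget gapped alignment that the basic bound retains."""

    def setup_method(self):
        self.fm = build_fm_index(FIG5_X)
        self.rev = build_fm_index(FIG5_X[::-1])
        self.basic = calculate_d_basic(FIG5_W, self.rev)
        auto = build_ac_automaton([FrequentPattern(FIG5_PATTERN, 2, 1)])
        self.dcdc = calculate_d_dcdc(FIG5_W, self.rev, auto)
        self.params = SearchParams(z=4, max_gap_extensions=3)

    def test_pattern_edit_value_is_truthful(self):
        from staligner.pruning import edit_distance_to_reference

        assert edit_distance_to_reference(FIG5_PATTERN, FIG5_X) == 2

    def test_bounds_at_the_critical_position(self):
        assert self.basic[FIG5_CRITICAL] == 2
        assert self.dcdc[FIG5_CRITICAL] == 3
        # Both bounds are valid under the extension-charging metric.
        from oracles import dp_min_cost_prefix

        oracle = dp_min_cost_prefix(FIG5_W, FIG5_X)
        for i in range(len(FIG5_W)):
            assert self.basic[i] <= oracle[i]
            assert self.dcdc[i] <= oracle[i]

    def test_basic_pruning_keeps_the_gapped_alignment(self):
        hits = inexact_search(FIG5_W, self.fm, self.basic, self.params)
        target = [
            h for h in hits if FIG5_TARGET_POS in self.fm.locate(h.interval)
        ]
        assert target and min(h.diff for h in target) == 4

    def test_dcdc_pruning_discards_it(self):
        hits = inexact_search(FIG5_W, self.fm, self.dcdc, self.params)
        assert FIG5_TARGET_POS not in positions_of(self.fm, hits)

    def test_unpruned_search_agrees_with_basic(self):
        hits = inexact_search(FIG5_W, self.fm, None, self.params)
        assert FIG5_TARGET_POS in positions_of(self.fm, hits)


class TestMappingQuality:
    def test_unique_exact_hit(self):
        assert mapping_quality(1, 0) == 37

    def test_co_optimal_hits(self):
        assert mapping_quality(2, 0) == 0
        assert mapping_quality(5, 3) == 0

    def test_decreasing_in_runner_up_count(self):
        quals = [mapping_quality(1, s) for s in range(0, 12)]
        assert all(0 <= q <= 60 for q in quals)
        assert all(a >= b for a, b in zip(quals, quals[1:]))


class TestAlignRead:
    def test_unique_forward_substring(self, rng):
        x = random_dna(rng, 800)
        bundle = make_bundle(x)
        start = 100
        read = Sequence("r1", x[start : start + 40])
        (hit,) = align_read(read, bundle, SearchParams(z=2))
        assert hit.mapped and hit.strand == "+"
        assert hit.pos == start and hit.diff_count == 0
        assert hit.mapq >= 10

    def test_reverse_complement_read(self, rng):
        x = random_dna(rng, 800)
        bundle = make_bundle(x)
        start = 200
        read = Sequence("r2", revcomp(x[start : start + 40]))
        (hit,) = align_read(read, bundle, SearchParams(z=2))
        assert hit.mapped and hit.strand == "-"
        assert hit.pos == start
        assert hit.seq == x[start : start + 40]

    def test_absent_read_is_unmapped(self, rng):
        x = random_dna(rng, 200)
        bundle = make_bundle(x)
        read = Sequence("r3", "ACGTACGTACGTACGTACGTACGTACGTACGT")
        if read.bases in x or revcomp(read.bases) in x:
            pytest.skip("coincidental containment")
        (hit,) = align_read(read, bundle, SearchParams(z=0))
        assert not hit.mapped

    def test_too_short_read_is_unmapped(self, rng):
        bundle = make_bundle(random_dna(rng, 100))
        (hit,) = align_read(Sequence("r4", "A"), bundle, SearchParams(z=1))
        assert not hit.mapped

    def test_duplicated_locus_gets_mapq_zero(self, rng):
        core = random_dna(rng, 60)
        x = random_dna(rng, 100) + core + random_dna(rng, 100) + core + random_dna(rng, 100)
        bundle = make_bundle(x)
        read = Sequence("r5", core[10:50])
        (hit,) = align_read(read, bundle, SearchParams(z=1))
        assert hit.mapped
        assert hit.n_cooptimal == 2
        assert hit.mapq == 0

    def test_mapq_confidence_consistency(self, rng):
        # A hit the evaluator would call confident (mapq >= 10) must be a
        # unique placement; ambiguous placements always score 0.
        x = random_dna(rng, 1000)
        bundle = make_bundle(x)
        for _ in range(10):
            start = rng.randrange(len(x) - 30)
            read = Sequence("r", plant_subs(rng, x[start : start + 30], rng.randint(0, 1)))
            (hit,) = align_read(read, bundle, SearchParams(z=2))
            assert hit.mapped
            if hit.mapq >= 10:
                assert hit.n_cooptimal == 1
            if hit.n_cooptimal > 1:
                assert hit.mapq == 0

    def test_results_invariant_to_sta(self, rng):
        x = random_dna(rng, 600)
        with_trie = make_bundle(x, with_trie=True)
        without = make_bundle(x, with_trie=False)
        for _ in range(8):
            start = rng.randrange(len(x) - 30)
            read = Sequence("r", plant_subs(rng, x[start : start + 30], rng.randint(0, 2)))
            (h1,) = align_read(read, with_trie, SearchParams(z=2))
            (h2,) = align_read(read, without, SearchParams(z=2))
            assert (h1.mapped, h1.pos, h1.strand, h1.diff_count, h1.mapq) == (
                h2.mapped,
                h2.pos,
                h2.strand,
                h2.diff_count,
                h2.mapq,
            )

    def test_primary_tie_break_is_lowest_coordinate(self, rng):
        core = random_dna(rng, 40)
        x = random_dna(rng, 50) + core + random_dna(rng, 50) + core + random_dna(rng, 50)
        bundle = make_bundle(x)
        (hit,) = align_read(Sequence("r", core), bundle, SearchParams(z=0))
        assert hit.pos == 50


class TestReplayScript:
    def test_identity_for_empty_script(self):
        assert replay_script("ACGT", ()) == "ACGT"

    def test_all_op_kinds(self):
        from staligner.aligner import EditOp

        # read ACGTACGT; sub at 1 -> C->G window base G; insertion at 3
        # (read T absent); deletions: two bases between 5 and 6.
        script = (
            EditOp("D", 5, "T"),  # recorded first = rightmost of the pair
            EditOp("D", 5, "G"),
            EditOp("I", 3, "T"),
            EditOp("S", 1, "G"),
        )
        assert replay_script("ACGTACGT", script) == "AGGACGTGT"
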