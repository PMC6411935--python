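"""Unique statistics, initial assignment, EM loop, score, fpkm,
aggregation — checked against hand arithmetic and a loop-explicit
brute-force reference on random instances."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telocus.alignio import CandidateSet, FragmentAlignments
from telocus.annotation import AnnotationSet, TELocus
from telocus.quant import (
    LocusEstimate,
    UniqueStats,
    aggregate_subfamilies,
    apply_score_threshold,
    compute_fpkm,
    compute_score,
    effective_length,
    em_step,
    initial_assignment,
    run_em,
    unique_stats,
)

from conftest import key, random_instance
from oracle_em import brute_em, brute_initial


def make_cands(read_id, spans_by_key):
    return CandidateSet(read_id=read_id, candidates=dict(spans_by_key))


def make_frag(read_id, uniqueness="unique", full_count=False):
    f = FragmentAlignments(read_id=read_id)
    f.uniqueness = uniqueness
    f.full_count = full_count
    return f


class TestUniqueStats:
    def test_counts_and_distinct_start_positions(self):
        """Four unique fragments at two distinct starts give C_U=4, L_U=2."""
        a = key("A")
        frags = [
            (make_frag(f"u{i}"), make_cands(f"u{i}", {a: [(s, s + 250)]}))
            for i, s in enumerate([100, 100, 400, 400])
        ]
        stats = unique_stats(frags)
        assert stats[a].c_u == 4
        assert stats[a].l_u == 2
        assert (stats[a].span_start, stats[a].span_end) == (100, 650)

    def test_single_fragment(self):
        a = key("A")
        stats = unique_stats(
            [(make_frag("u"), make_cands("u", {a: [(0, 250)]}))]
        )
        assert (stats[a].c_u, stats[a].l_u) == (1, 1)

    def test_no_fragments(self):
        assert unique_stats([]) == {}

    def test_full_count_pairs_add_counts_but_no_unique_length(self):
        """Rescued doubly-multi pairs contribute whole counts but their
        positions never enter the uniquely alignable length."""
        a = key("A")
        frags = [
            (make_frag("u0"), make_cands("u0", {a: [(100, 350)]})),
            (make_frag("f0", "multi", full_count=True),
             make_cands("f0", {a: [(700, 950)]})),
        ]
        stats = unique_stats(frags)
        assert stats[a].c_u == 1
        assert stats[a].c_full == 1
        assert stats[a].l_u == 1
        assert stats[a].base_count == 2.0
        # the span still tracks all certain placements
        assert stats[a].span_end == 950


class TestInitialAssignment:
    def test_worked_example_fractions(self, fig2):
        """The no-unique locus takes 1/N = 1/3; the remaining 2/3 splits
        2:1 by normalized unique counts, giving 4/9 and 2/9."""
        a, b, c = key("A"), key("B"), key("C")
        st_ = fig2.ustats
        assert st_[a].c_u / st_[a].l_u == 2.0
        assert st_[b].c_u / st_[b].l_u == 1.0
        table = initial_assignment(fig2.multi, fig2.ustats)
        for rid in fig2.multi:
            assert table[rid][c] == pytest.approx(1 / 3, abs=1e-12)
            assert table[rid][a] == pytest.approx(4 / 9, abs=1e-12)
            assert table[rid][b] == pytest.approx(2 / 9, abs=1e-12)
            assert sum(table[rid].values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_candidate_gets_everything(self):
        table = initial_assignment({"r": [key("A")]}, {})
        assert table["r"][key("A")] == 1.0

    def test_all_zero_unique_split_equally(self):
        keys = [key(x) for x in "ABCD"]
        table = initial_assignment({"r": keys}, {})
        assert all(f == 0.25 for f in table["r"].values())

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fractions_sum_to_one_and_are_nonnegative(self, data):
        n = data.draw(st.integers(2, 8))
        keys = [key(f"L{i}") for i in range(n)]
        ustats = {}
        for k in keys:
            c_u = data.draw(st.integers(0, 10))
            stc = UniqueStats(c_u=c_u)
            if c_u:
                stc.starts = set(range(data.draw(st.integers(1, c_u))))
            ustats[k] = stc
        subset = data.draw(st.sets(st.sampled_from(keys), min_size=1))
        table = initial_assignment({"r": list(subset)}, ustats)
        fr = table["r"]
        assert all(f >= 0 for f in fr.values())
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force(self):
        rng = random.Random(7)
        for _ in range(25):
            _, ustats, _, _, multi = random_instance(rng)
            cu = {k: s.c_u for k, s in ustats.items()}
            lu = {k: s.l_u for k, s in ustats.items()}
            ours = initial_assignment(multi, ustats)
            ref = brute_initial(cu, lu, multi)
            for rid in multi:
                for k in multi[rid]:
                    assert ours[rid].get(k, 0.0) == pytest.approx(
                        ref[rid].get(k, 0.0), abs=1e-12
                    )


class TestEffectiveLength:
    @pytest.mark.parametrize(
        "L,l_avg,expected", [(6000, 250, 5751), (250, 250, 1), (200, 250, 1)]
    )
    def test_formula_and_clamp(self, L, l_avg, expected):
        assert effective_length(L, l_avg) == expected


class TestEmStep:
    def test_zeroing_gives_all_to_the_surviving_candidate(self):
        keys = [key("A"), key("B"), key("C")]
        counts = {keys[0]: 10.0, keys[1]: 0.4, keys[2]: 0.4}
        eff = {k: 100.0 for k in keys}
        table = em_step({"r": keys}, counts, eff)
        assert table["r"][keys[0]] == 1.0
        assert table["r"][keys[1]] == 0.0

    def test_equal_normalized_counts_split_equally(self):
        a, b = key("A"), key("B")
        table = em_step({"r": [a, b]}, {a: 6.0, b: 3.0}, {a: 200.0, b: 100.0})
        assert table["r"][a] == pytest.approx(0.5)

    def test_all_below_one_falls_back_to_equal_split(self):
        keys = [key("A"), key("B")]
        table = em_step({"r": keys}, {k: 0.3 for k in keys}, {k: 10.0 for k in keys})
        assert all(f == 0.5 for f in table["r"].values())


class TestRunEm:
    def test_zero_iterations_reproduces_initial_totals(self, fig2):
        a, b, c = key("A"), key("B"), key("C")
        fr0 = initial_assignment(fig2.multi, fig2.ustats)
        counts, _, info = run_em(
            fig2.base, fr0, fig2.eff_len, fig2.multi, iterations=0
        )
        assert counts[a] == pytest.approx(4 + 4 * 4 / 9)   # ~5.778
        assert counts[b] == pytest.approx(1 + 4 * 2 / 9)   # ~1.889
        assert counts[c] == pytest.approx(4 / 3)           # ~1.333
        assert info["iterations"] == 0

    def test_single_locus_is_a_fixed_point(self):
        a = key("A")
        fr0 = {"r1": {a: 1.0}, "r2": {a: 1.0}}
        counts, _, info = run_em(
            {a: 3.0}, fr0, {a: 500.0}, iterations="auto"
        )
        assert counts[a] == pytest.approx(5.0)
        assert info["converged"]

    def test_read_conservation_at_every_iteration(self):
        """Total counts never exceed the number of fragments; equality
        holds whenever no candidate has been zeroed."""
        rng = random.Random(11)
        for _ in range(20):
            _, ustats, base, eff, multi = random_instance(rng, max_frags=40)
            total = sum(base.values()) + len(multi)
            for it in range(0, 6):
                counts, fractions, _ = run_em(
                    base, initial_assignment(multi, ustats), eff, multi,
                    iterations=it,
                )
                assert sum(counts.values()) <= total + 1e-9
                for rid in multi:
                    s = sum(fractions[rid].values())
                    assert -1e-12 <= s <= 1.0 + 1e-12

    @pytest.mark.parametrize("zeroing", ["per-step", "final"])
    @pytest.mark.parametrize("iterations", [0, 1, 3, 17, "auto"])
    def test_matches_brute_force_reference(self, iterations, zeroing):
        """The EM implementation agrees with the loop-explicit brute-force
        evaluation to 1e-9 on random small instances."""
        rng = random.Random(hash((str(iterations), zeroing)) % (2**31))
        for _ in range(25):
            _, ustats, base, eff, multi = random_instance(rng)
            cu = {k: s.c_u for k, s in ustats.items()}
            lu = {k: s.l_u for k, s in ustats.items()}
            counts, _, _ = run_em(
                base, initial_assignment(multi, ustats), eff, multi,
                iterations=iterations, zeroing=zeroing,
            )
            ref_counts, _ = brute_em(
                base, cu, lu, eff, multi, iterations, zeroing=zeroing
            )
            all_keys = set(counts) | set(ref_counts)
            for k in all_keys:
                assert counts.get(k, 0.0) == pytest.approx(
                    ref_counts.get(k, 0.0), abs=1e-9
                )

    def test_em_concentrates_on_the_unique_backed_locus(self):
        """With shared multi reads and unique evidence at one locus only,
        EM drives the other locus's fraction toward zero."""
        a, b = key("A"), key("B")
        multi = {f"m{i}": [a, b] for i in range(20)}
        ustats = {a: UniqueStats(c_u=10, starts=set(range(5)))}
        base = {a: 10.0, b: 0.0}
        eff = {a: 1000.0, b: 1000.0}
        fr0 = initial_assignment(multi, ustats)
        counts0, _, _ = run_em(base, fr0, eff, multi, iterations=0)
        counts, _, info = run_em(base, fr0, eff, multi, iterations="auto")
        assert counts[b] < counts0[b]
        assert counts[b] == pytest.approx(0.0, abs=1e-6)
        assert counts[a] == pytest.approx(30.0, abs=1e-6)


class TestScoreFpkm:
    def test_score_definition_and_bounds(self):
        assert compute_score(5, 10) == 50
        assert compute_score(10, 10) == 100
        with pytest.raises(ValueError):
            compute_score(1, 0)

    def test_worked_example_scores(self, fig2):
        a, b, c = key("A"), key("B"), key("C")
        fr0 = initial_assignment(fig2.multi, fig2.ustats)
        counts, _, _ = run_em(fig2.base, fr0, fig2.eff_len, fig2.multi,
                              iterations=0)
        assert compute_score(counts[c], fig2.r_te[c]) == pytest.approx(
            100 / 3, abs=0.05
        )
        assert compute_score(counts[a], fig2.r_te[a]) == pytest.approx(
            72.22, abs=0.05
        )

    def test_fpkm_unit_case_and_scaling(self):
        assert compute_fpkm(10, 1000, 10**6) == pytest.approx(10.0)
        assert compute_fpkm(0, 1000, 10**6) == 0.0
        assert compute_fpkm(10, 1000, 2 * 10**6) == pytest.approx(5.0)


def make_estimate(locus: TELocus, orientation="sense", c_te=5.0, r_te=10,
                  fpkm=1.0):
    return LocusEstimate(
        locus_id=locus.locus_id, orientation=orientation, chrom=locus.chrom,
        tx_start=locus.start, tx_end=locus.end, tx_strand=locus.strand,
        subfamily=locus.subfamily, family=locus.family, clazz=locus.clazz,
        milli_div=locus.milli_div, c_u=1, c_te=c_te, r_te=r_te,
        length_transcribed=float(len(locus)), frag_len_mean=250.0,
        length_effective=float(len(locus)) - 249.0,
        score=100.0 * c_te / r_te, fpkm=fpkm,
    )


class TestAggregation:
    def loci(self):
        return [
            TELocus("chr1", 0, 1000, "+", "AluYa5", "Alu", "SINE"),
            TELocus("chr1", 2000, 3000, "-", "AluYa5", "Alu", "SINE"),
            TELocus("chr1", 5000, 7000, "+", "L1HS", "L1", "LINE"),
        ]

    def test_totals_and_conservation(self):
        loci = self.loci()
        ann = AnnotationSet(loci)
        ests = {
            (loci[0].locus_id, "sense"): make_estimate(loci[0], c_te=3.0),
            (loci[1].locus_id, "sense"): make_estimate(loci[1], c_te=7.0),
            (loci[2].locus_id, "sense"): make_estimate(loci[2], c_te=12.0),
        }
        summaries = {s.subfamily: s for s in aggregate_subfamilies(ests, ann)}
        assert summaries["AluYa5"].total_count == pytest.approx(10.0)
        assert summaries["L1HS"].total_count == pytest.approx(12.0)
        total = sum(s.total_count for s in summaries.values())
        assert total == pytest.approx(sum(e.c_te for e in ests.values()))
        assert summaries["AluYa5"].n_loci_expressed == 0  # 3 and 7 both < 10
        assert summaries["L1HS"].n_loci_expressed == 1

    def test_orientations_collapse_per_locus(self):
        loci = self.loci()
        ann = AnnotationSet(loci)
        ests = {
            (loci[0].locus_id, "sense"): make_estimate(loci[0], c_te=6.0),
            (loci[0].locus_id, "antisense"): make_estimate(
                loci[0], orientation="antisense", c_te=6.0
            ),
        }
        (summary,) = aggregate_subfamilies(ests, ann)
        assert summary.total_count == pytest.approx(12.0)
        assert summary.n_loci_expressed == 1  # one locus, 12 >= 10

    def test_empty_estimates(self):
        assert aggregate_subfamilies({}, AnnotationSet(self.loci())) == []

    def test_unknown_locus_rejected(self):
        stray = TELocus("chrX", 0, 100, "+", "Zzz", "Z", "DNA")
        ests = {(stray.locus_id, "sense"): make_estimate(stray)}
        with pytest.raises(KeyError):
            aggregate_subfamilies(ests, AnnotationSet(self.loci()))


class TestScoreThreshold:
    def make(self, scores):
        loci = [
            TELocus("chr1", i * 1000, i * 1000 + 500, "+", f"S{i}", "F", "SINE")
            for i in range(len(scores))
        ]
        return {
            (l.locus_id, "sense"): make_estimate(l, c_te=s / 10.0, r_te=10)
            for l, s in zip(loci, scores)
        }

    def test_zero_threshold_is_identity(self):
        ests = self.make([10, 60, 100])
        out = apply_score_threshold(ests, threshold=0)
        assert set(out) == set(ests)
        assert not any(e.low_score for e in out.values())

    def test_full_threshold_passes_only_all_unique(self):
        ests = self.make([99.9, 100])
        out = apply_score_threshold(ests, threshold=100)
        flags = sorted(e.low_score for e in out.values())
        assert flags == [False, True]

    def test_drop_removes_low_score_loci(self):
        ests = self.make([30, 70])
        out = apply_score_threshold(ests, threshold=50, drop=True)
        assert len(out) == 1
        (kept,) = out.values()
        assert kept.score == pytest.approx(70)
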