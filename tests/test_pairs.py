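import numpy as np
import pandas as pd
from hypothesis import given, strategies as st

from cnepairs.io import GenomicInterval, GtfFeature
from cnepairs.pairs import (ConservedElement, build_pairs,
                            classify_conservation, classify_elements,
                            element_id, find_ao_pairs, merge_and_filter,
                            rbh_orthologs)


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


class TestMergeAndFilter:
    def test_gap_rule_manual_oracle(self):
        out = merge_and_filter([iv(100, 250), iv(300, 420), iv(1000, 1100)])
        assert out == [iv(100, 420), iv(1000, 1100)]  # gap 50 merges, 580 not

    def test_gap_99_merges_gap_100_does_not(self):
        assert merge_and_filter([iv(0, 150), iv(249, 400)]) == [iv(0, 400)]
        assert merge_and_filter([iv(0, 150), iv(250, 400)]) == [iv(0, 150), iv(250, 400)]

    def test_short_elements_removed_after_merge(self):
        assert merge_and_filter([iv(0, 99)]) == []
        # two short pieces merging into a long one survive
        assert merge_and_filter([iv(0, 60), iv(80, 160)]) == [iv(0, 160)]

    def test_unsorted_input_sorted_internally(self):
        out = merge_and_filter([iv(1000, 1100), iv(100, 250)])
        assert out == [iv(100, 250), iv(1000, 1100)]

    @given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 400)),
                    min_size=1, max_size=30))
    def test_idempotent(self, spans):
        ivs = [iv(s, s + l) for s, l in spans]
        once = merge_and_filter(ivs)
        assert merge_and_filter(once) == once


GTF = [
    GtfFeature("gene", iv(1000, 5000), "+", "g1", "protein_coding"),
    GtfFeature("exon", iv(1000, 1200), "+", "g1", "protein_coding"),
    GtfFeature("UTR", iv(1200, 1300), "+", "g1", "protein_coding"),
    # a non-coding gene must not classify anything
    GtfFeature("gene", iv(8000, 9000), "+", "g2", "lincRNA"),
    GtfFeature("exon", iv(8000, 9000), "+", "g2", "lincRNA"),
]


class TestClassifyElements:
    def test_precedence_exon_over_intron(self):
        els = classify_elements([iv(1100, 1500)], GTF)  # exon + UTR + intron
        assert els[0].category == "exon"
        assert not els[0].is_cne

    def test_utr_then_intron_then_intergenic(self):
        cats = [e.category for e in classify_elements(
            [iv(1250, 1400), iv(2000, 2100), iv(6000, 6100), iv(8100, 8200)], GTF)]
        assert cats == ["UTR", "intron", "intergenic", "intergenic"]


def ce(s, e, cat="intergenic"):
    i = iv(s, e)
    return ConservedElement(element_id(i), i, cat)


class TestBuildPairs:
    def test_consecutive_cnes_chain(self):
        pairs = build_pairs([ce(0, 200), ce(500, 700), ce(1000, 1200)])
        assert [(p.left.interval.start, p.right.interval.start) for p in pairs] \
            == [(0, 500), (500, 1000)]
        assert pairs[0].inter_cne == iv(200, 500)
        assert pairs[0].d_h == 500

    def test_coding_element_breaks_adjacency(self):
        pairs = build_pairs([ce(0, 200), ce(500, 700, "exon"), ce(1000, 1200)])
        assert pairs == []

    def test_long_member_excluded(self):
        pairs = build_pairs([ce(0, 1200), ce(2000, 2300)])
        assert pairs == []

    def test_every_pair_satisfies_length_and_distance_invariants(self):
        els = [ce(i * 3000, i * 3000 + 100 + 50 * (i % 10)) for i in range(30)]
        for p in build_pairs(els):
            assert 100 <= p.left.interval.length <= 1000
            assert 100 <= p.right.interval.length <= 1000
            assert p.d_h > 0


def brute_force_rbh(fwd, rev, query_intervals):
    """All-pairs reciprocal-best check, independent of the dict-based path."""
    out = {}
    for (q, sp) in {(r["query"], r["species"]) for r in fwd.to_dict("records")}:
        rows = [r for r in fwd.to_dict("records")
                if r["query"] == q and r["species"] == sp]
        best = sorted(rows, key=lambda r: (-r["score"], r["start"], r["chrom"]))[0]
        tkey = f"{sp}:{best['chrom']}:{best['start']}-{best['end']}"
        back = [r for r in rev.to_dict("records") if r["query"] == tkey]
        if not back:
            continue
        bb = sorted(back, key=lambda r: (-r["score"], r["start"], r["chrom"]))[0]
        qiv = query_intervals[q]
        biv = GenomicInterval(bb["chrom"], bb["start"], bb["end"])
        if biv.overlap_length(qiv) >= 1:
            out.setdefault(q, {})[sp] = GenomicInterval(
                best["chrom"], best["start"], best["end"])
    return out


class TestRbhOrthologs:
    Q = {"q1": iv(100, 300)}

    def _tables(self, rev_rows):
        fwd = pd.DataFrame(
            [["q1", "mouse", "chrM", 500, 700, 95.0],
             ["q1", "mouse", "chrM", 900, 1100, 60.0]],
            columns=["query", "species", "chrom", "start", "end", "score"])
        rev = pd.DataFrame(rev_rows,
                           columns=["query", "species", "chrom", "start", "end", "score"])
        return fwd, rev

    def test_accepted_when_reverse_best_overlaps(self):
        fwd, rev = self._tables([["mouse:chrM:500-700", "focal", "chr1", 150, 350, 90.0]])
        out = rbh_orthologs(fwd, rev, self.Q)
        assert out["q1"]["mouse"] == iv(500, 700, "chrM")

    def test_rejected_when_reverse_maps_elsewhere(self):
        fwd, rev = self._tables([["mouse:chrM:500-700", "focal", "chr1", 5000, 5200, 90.0]])
        assert rbh_orthologs(fwd, rev, self.Q) == {}

    def test_no_forward_hits_no_ortholog(self):
        fwd = pd.DataFrame([], columns=["query", "species", "chrom", "start", "end", "score"])
        assert rbh_orthologs(fwd, fwd, self.Q) == {}

    def test_matches_brute_force_on_random_tables(self, rng):
        queries = {f"q{i}": iv(1000 * i, 1000 * i + 200) for i in range(5)}
        fwd_rows, rev_rows = [], []
        for _ in range(60):
            q = f"q{rng.integers(5)}"
            sp = ["mouse", "dog"][rng.integers(2)]
            s = int(rng.integers(0, 50)) * 100
            fwd_rows.append([q, sp, "chrT", s, s + 200, float(rng.integers(50, 100))])
        for _ in range(60):
            s = int(rng.integers(0, 50)) * 100
            sp = ["mouse", "dog"][rng.integers(2)]
            tkey = f"{sp}:chrT:{s}-{s + 200}"
            bs = int(rng.integers(0, 8)) * 1000
            rev_rows.append([tkey, "focal", "chr1", bs, bs + 200,
                             float(rng.integers(50, 100))])
        cols = ["query", "species", "chrom", "start", "end", "score"]
        fwd = pd.DataFrame(fwd_rows, columns=cols)
        rev = pd.DataFrame(rev_rows, columns=cols)
        assert rbh_orthologs(fwd, rev, queries) == brute_force_rbh(fwd, rev, queries)


class TestClassifyConservation:
    SPECIES = ["human", "platypus", "chicken", "frog", "dog"]

    def _pair(self):
        return build_pairs([ce(0, 200), ce(5000, 5200)])[0]

    def _omap(self, **by_species):
        p = self._pair()
        out = {p.left.element_id: {}, p.right.element_id: {}}
        for sp, dist in by_species.items():
            out[p.left.element_id][sp] = iv(10_000, 10_200, "c2")
            out[p.right.element_id][sp] = iv(10_000 + dist, 10_200 + dist, "c2")
        return [p], out

    def test_platypus_makes_mammalian(self):
        pairs, omap = self._omap(platypus=3000)
        out = classify_conservation(pairs, omap, self.SPECIES)
        assert out[0].conservation == "mammalian"
        assert out[0].species_distance["platypus"] == 3000

    def test_two_nonmammals_make_deeply(self):
        pairs, omap = self._omap(chicken=4000, frog=2500)
        out = classify_conservation(pairs, omap, self.SPECIES)
        assert out[0].conservation == "deeply"

    def test_distance_cap_discards_pair(self):
        pairs, omap = self._omap(dog=260_000, platypus=3000)
        assert classify_conservation(pairs, omap, self.SPECIES) == []

    def test_no_orthologs_is_neither(self):
        pairs, omap = self._omap()
        out = classify_conservation(pairs, omap, self.SPECIES)
        assert out[0].conservation == "neither"


class TestAoPairs:
    def _setup(self, with_intervening=False):
        pa = build_pairs([ce(0, 200), ce(5000, 5200)])
        pa[0].nrdd_group = 2
        b_left, b_right = ce(100_000, 100_200), ce(104_000, 104_200)
        elements_b = [b_left, b_right]
        if with_intervening:
            elements_b.append(ce(102_000, 102_150))
        pb = build_pairs(elements_b)
        for p in pb:
            p.nrdd_group = 9
        omap = {
            pa[0].left.element_id: {"mouse": b_left.interval},
            pa[0].right.element_id: {"mouse": b_right.interval},
        }
        return pa, pb, omap, elements_b

    def test_ao_pair_found_and_categorized(self):
        pa, pb, omap, els = self._setup()
        out = find_ao_pairs(pa, pb, omap, "mouse", els)
        assert len(out) == 1
        assert out[0][2] == "H1-3; M8-10"

    def test_intervening_element_blocks_ao(self):
        pa, pb, omap, els = self._setup(with_intervening=True)
        assert find_ao_pairs(pa, pb, omap, "mouse", els) == []
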