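"""Rix discovery, inversion enumeration, allele calling, read support."""

import numpy as np
import pytest

from pforge import shufflon, synthetic
from pforge._seq import revcomp
from pforge.errors import InputError, RecombinationError, StateSpaceOverflow
from pforge.shufflon import (
    MINUS,
    PLUS,
    ShufflonCassette,
    active_allele,
    count_distinct_alleles,
    detect_inversions,
    enumerate_states,
    find_rix_sites,
    invert_between,
    rv_identity_matrix,
    variant_read_support,
)

import oracles

MOTIF = "TTCCCTAACCC"


def toy_cassette(orientations=("+", "+", "-", "-"), segs=None):
    """Small cassette: head, rix/seg alternation per `orientations`."""
    if segs is None:
        segs = {"s1": "AAGGAAGGAAGG", "s2": "CCAACCAACCAA", "s3": "GGTTGGTTGGTT"}
    items = []
    seg_ids = sorted(segs)
    for i, o in enumerate(orientations):
        items.append(("rix", o))
        if i < len(seg_ids) and i < len(orientations) - 1:
            items.append(("seg", seg_ids[i], PLUS))
    return ShufflonCassette(
        rc_head="ATGGCTGCA",
        motif=min(MOTIF, revcomp(MOTIF)),
        items=tuple(items),
        segments=segs,
        tail="TTGACA",
    )


class TestFindRixSites:
    def test_planted_motif_orientations(self, random_dna):
        rng = np.random.default_rng(42)
        parts = []
        planted = []
        pos = 0
        for orient in ("+", "-", "+", "-", "+"):
            spacer = "".join(rng.choice(list("ACGT"), 150))
            occ = MOTIF if orient == "+" else revcomp(MOTIF)
            parts.extend([spacer, occ])
            pos += len(spacer)
            planted.append((pos, orient))
            pos += len(MOTIF)
        parts.append("".join(rng.choice(list("ACGT"), 150)))
        locus = "".join(parts)

        sites = find_rix_sites(locus, min_len=11, min_count=3)
        canon = min(MOTIF, revcomp(MOTIF))
        found = [
            (s.position, s.orientation if canon == MOTIF
             else (PLUS if s.orientation == MINUS else MINUS))
            for s in sites
            if s.motif == canon
        ]
        assert found == planted

    def test_random_locus_has_no_long_repeats(self, random_dna):
        locus = random_dna(2000, seed=7)
        sites = find_rix_sites(locus, min_len=11, min_count=3)
        assert sites == []
        # cross-check by exhaustive canonical k-mer counting
        counts = {}
        for i in range(len(locus) - 10):
            km = locus[i : i + 11]
            canon = min(km, revcomp(km))
            counts[canon] = counts.get(canon, 0) + 1
        assert max(counts.values()) < 3

    def test_palindromic_motif_excluded(self):
        pal = "ACGCGCGCGT"
        assert pal == revcomp(pal)
        rng = np.random.default_rng(3)
        locus = "".join(
            "".join(rng.choice(list("ACGT"), 120)) + pal for _ in range(4)
        )
        sites = find_rix_sites(locus, min_len=len(pal), min_count=3)
        assert all(s.motif != pal for s in sites)


class TestInvertBetween:
    def test_involution(self):
        cas = toy_cassette()
        st = cas.reference_state()
        once = invert_between(st, 1, 2)
        twice = invert_between(once, 1, 2)
        assert twice.sequence == st.sequence

    def test_middle_segment_reverse_complemented(self):
        cas = toy_cassette(orientations=("+", "-", "+"))
        st = cas.reference_state()
        flipped = invert_between(st, 0, 1)
        seg = cas.segments["s1"]
        assert revcomp(seg) in flipped.sequence
        # flanks unchanged
        assert flipped.sequence.startswith(cas.rc_head)
        assert flipped.sequence.endswith(cas.tail)

    def test_direct_pair_rejected(self):
        cas = toy_cassette(orientations=("+", "+", "-"))
        with pytest.raises(RecombinationError):
            invert_between(cas.reference_state(), 0, 1)

    def test_contained_rix_orientations_flip(self):
        cas = toy_cassette(orientations=("+", "-", "-", "-"))
        st = cas.reference_state()
        flipped = invert_between(st, 0, 3)
        assert flipped.rix_orientations() == ("+", "+", "+", "-")


class TestEnumerateStates:
    def test_all_direct_cassette_is_frozen(self):
        cas = toy_cassette(orientations=("+", "+", "+"))
        states = enumerate_states(cas)
        assert len(states) == 1

    def test_single_inverted_pair_two_states(self):
        cas = toy_cassette(orientations=("+", "-"), segs={"s1": "AAGGAAGGAAGG"})
        states = enumerate_states(cas)
        assert len(states) == 2

    def test_matches_string_bfs_oracle(self):
        layouts = [
            ("+", "-"),
            ("+", "+", "-"),
            ("+", "-", "+", "-"),
            ("+", "+", "-", "-"),
            ("+", "+", "-", "-", "-"),
        ]
        for orients in layouts:
            cas = toy_cassette(orientations=orients)
            states = enumerate_states(cas)
            oracle = oracles.shufflon_string_closure(
                cas.reference_state().sequence, MOTIF
            )
            assert {s.sequence for s in states} == oracle

    def test_segment_multiset_conserved(self):
        cas = toy_cassette(orientations=("+", "+", "-", "-"))
        ref_segs = sorted(
            min(s, revcomp(s)) for s in cas.segments.values()
        )
        for st in enumerate_states(cas):
            segs = sorted(
                min(cas.segments[it[1]], revcomp(cas.segments[it[1]]))
                for it in st.items
                if it[0] == "seg"
            )
            assert segs == ref_segs

    def test_overflow_raises(self):
        cas = toy_cassette(orientations=("+", "+", "-", "-"))
        with pytest.raises(StateSpaceOverflow):
            enumerate_states(cas, max_states=2)


class TestActiveAllele:
    def test_reference_state_fuses_first_segment(self):
        locus, cas, truth = synthetic.make_shufflon(2, n_rv=3)
        allele = active_allele(cas.reference_state())
        assert allele == truth.expected["allele_proteins"]["Rv1"]

    def test_reverse_complement_segment_is_invalid(self):
        locus, cas, truth = synthetic.make_shufflon(2, n_rv=3)
        st = cas.reference_state()
        # flip only the active segment (simulate an off-pathway state)
        items = list(st.items)
        items[1] = ("seg", items[1][1], MINUS if items[1][2] == PLUS else PLUS)
        bad = shufflon.InversionState(cassette=cas, items=tuple(items))
        assert active_allele(bad) is None

    def test_degenerate_head_only_cassette(self):
        # in-gene rix immediately followed by a stop codon: Rc-only protein
        head = "ATGGCTGCTG"  # len 10; 10 + 11 = 21, multiple of 3
        cas = ShufflonCassette(
            rc_head=head,
            motif=min(MOTIF, revcomp(MOTIF)),
            items=(("rix", MINUS if min(MOTIF, revcomp(MOTIF)) != MOTIF else PLUS),
                   ("seg", "s", PLUS)),
            segments={"s": "TAAGGGCCC"},
            tail="",
        )
        st = cas.reference_state()
        prot = active_allele(st)
        assert prot is not None
        from pforge._seq import translate
        assert prot == translate(head + MOTIF)

    def test_missing_in_gene_rix_errors(self):
        cas = toy_cassette()
        st = cas.reference_state()
        no_rix = shufflon.InversionState(cassette=cas, items=st.items[1:])
        with pytest.raises(InputError):
            active_allele(no_rix)


class TestCountDistinctAlleles:
    def test_five_variant_architecture_yields_five(self):
        _, cas, truth = synthetic.make_shufflon(2, n_rv=5)
        assert count_distinct_alleles(cas) == 5

    def test_all_direct_cassette_one_allele(self):
        _, cas, _ = synthetic.make_shufflon(3, n_rv=1)
        assert count_distinct_alleles(cas) == 1

    def test_unreachable_segment_not_counted(self):
        # 3 Rv but the third has a direct rix: no inverted partner swaps it in
        _, cas5, _ = synthetic.make_shufflon(4, n_rv=3)
        items = []
        for it in cas5.items:
            items.append(it)
        # make the last rix direct (same orientation as the in-gene rix)
        first = items[0][1]
        items[-1] = ("rix", first)
        items[-2] = ("seg", items[-2][1], PLUS if items[-2][2] == MINUS else MINUS)
        # now Rv3 sits forward between two direct rix sites: inversion can
        # no longer fuse it intact onto Rc (flip orientation mismatch)
        cas = ShufflonCassette(
            rc_head=cas5.rc_head, motif=cas5.motif, items=tuple(items),
            segments=cas5.segments, roles=cas5.roles, tail=cas5.tail,
        )
        assert count_distinct_alleles(cas) == 2


class TestDetectInversions:
    def test_identity(self, random_dna):
        s = random_dna(800, seed=1)
        blocks = detect_inversions(s, s)
        assert len(blocks) == 1
        assert blocks[0][2] == "+"
        assert blocks[0][0] == (0, 800)

    def test_planted_middle_inversion(self, random_dna):
        a = random_dna(900, seed=2)
        b = a[:300] + revcomp(a[300:600]) + a[600:]
        blocks = detect_inversions(a, b, anchor_k=15)
        strands = [s for _, _, s in blocks]
        assert strands == ["+", "-", "+"]
        (a_iv, _, _) = blocks[1]
        assert abs(a_iv[0] - 300) < 15
        assert abs(a_iv[1] - 600) < 15

    def test_flip_junctions_at_rix_sites(self):
        locus_ref, cas, _ = synthetic.make_shufflon(8, n_rv=3)
        st = cas.reference_state()
        flipped = invert_between(st, 0, 2)
        blocks = detect_inversions(locus_ref, flipped.sequence, anchor_k=15)
        inverted = [a for a, _, s in blocks if s == "-"]
        assert inverted
        rix_pos = [p for p, _ in
                   synthetic._locate_rix(locus_ref, cas.motif)]
        for start, end in inverted:
            assert any(abs(start - (p + len(cas.motif))) < 15 for p in rix_pos)
            assert any(abs(end - p) < 15 for p in rix_pos)

    def test_no_shared_anchors_empty(self, random_dna):
        a = random_dna(300, seed=3)
        b = random_dna(300, seed=4)
        assert detect_inversions(a, b) == []
        assert oracles.shared_unique_kmers(a, b, 15) == set()


class TestRvIdentityMatrix:
    def test_identical_and_substituted(self):
        m = rv_identity_matrix(["ACDEFG", "ACDEFG", "ACDEYG"])
        assert m[0, 1] == 100.0
        assert round(m[0, 2], 1) == 83.3
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 100.0)

    def test_zero_identity_pair(self):
        m = rv_identity_matrix(["AAAA", "GGGG"])
        assert m[0, 1] == 0.0

    def test_empty_protein_errors(self):
        with pytest.raises(InputError):
            rv_identity_matrix(["ACDE", ""])


class TestVariantReadSupport:
    @staticmethod
    def _variant_pair(seed=5):
        rng = np.random.default_rng(seed)
        left = "".join(rng.choice(list("ACGT"), 60))
        mid = "".join(rng.choice(list("ACGT"), 60))
        right = "".join(rng.choice(list("ACGT"), 60))
        v1 = left + mid + right
        v2 = left + revcomp(mid) + right
        return {"v1": v1, "v2": v2}

    def test_pure_source_assigns_to_one_variant(self):
        refs = self._variant_pair()
        reads, _ = synthetic.make_reads(
            11, refs["v1"], read_len=100, n_reads=400
        )
        counts = variant_read_support(reads, refs, junction_flank=10)
        assert counts["v2"] == 0
        assert counts["v1"] > 0

    def test_mixture_recovered_within_binomial_ci(self):
        refs = self._variant_pair()
        reads, truth = synthetic.make_reads(
            11, refs, weights={"v1": 0.7, "v2": 0.3},
            read_len=100, n_reads=2000,
        )
        counts = variant_read_support(reads, refs, junction_flank=10)
        total = counts["v1"] + counts["v2"]
        assert total > 0
        phat = counts["v1"] / total
        # binomial 99% CI around 0.7
        half = 2.576 * np.sqrt(0.7 * 0.3 / total)
        assert abs(phat - 0.7) <= half + 0.02

    def test_non_spanning_reads_excluded(self):
        refs = self._variant_pair()
        # reads only from the shared left flank: span no junction
        reads = [refs["v1"][:40], refs["v1"][5:45]]
        counts = variant_read_support(reads, refs, junction_flank=10)
        assert sum(counts.values()) == 0

    def test_flank_longer_than_reads_errors(self):
        refs = self._variant_pair()
        with pytest.raises(InputError):
            variant_read_support(["ACGTACGT"], refs, junction_flank=50)
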