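"""Attachment-site alignment, crossover inference and excision surgery."""

import numpy as np
import pytest

from pforge import attsite, catalog, synthetic
from pforge._seq import translate
from pforge.attsite import CrossoverWindow, ProphageRecord
from pforge.errors import AlignmentError, CrossoverError, InputError

import oracles

DNAJ2 = catalog.ATT_SITES["dnaJ2"]
TRNA_MET = catalog.ATT_SITES["tRNA-Met"]["Bb423phi2/689b-1"]
TMRNA = catalog.ATT_SITES["tmRNA"]["Bb447phi1/Bb1192phi1"]


class TestAlignAttPair:
    @pytest.mark.parametrize(
        "attL,attR,core,mism,indels",
        [
            # reported 35 bp cores with 5-7 mismatches at the chaperone locus
            (DNAJ2["Bb48phi1"]["attL"], DNAJ2["Bb48phi1"]["attR"], 35, 7, 0),
            # single difference between the tRNA-Met 39-mers
            (TRNA_MET["attL"], TRNA_MET["attR"], 39, 1, 0),
            # identity case
            ("ACGTACGTACGT", "ACGTACGTACGT", 12, 0, 0),
        ],
    )
    def test_printed_pairs(self, attL, attR, core, mism, indels):
        pair = attsite.align_att_pair(attL, attR)
        assert (pair.core_length, pair.mismatches, pair.indels) == (core, mism, indels)
        assert pair.matches + pair.mismatches + pair.indels == pair.core_length

    def test_one_base_deletion_flagged_not_rejected(self):
        # two reported attR entries are 34 bp among 35 bp homologs
        sites = DNAJ2["Bb423phi1"]
        pair = attsite.align_att_pair(sites["attL"], sites["attR"])
        assert pair.indels == 1
        assert not pair.gaps_exceeded
        pair0 = attsite.align_att_pair(sites["attL"], sites["attR"], max_gaps=0)
        assert pair0.gaps_exceeded

    def test_rejects_non_dna(self):
        with pytest.raises(InputError):
            attsite.align_att_pair("ACGTX", "ACGT")

    def test_matches_bruteforce_edit_script_on_reported_pairs(self):
        for locus in catalog.ATT_SITES.values():
            for sites in locus.values():
                pair = attsite.align_att_pair(sites["attL"], sites["attR"])
                dist, gaps = oracles.edit_distance_and_min_gaps(
                    sites["attL"], sites["attR"]
                )
                assert pair.total_differences == dist
                assert pair.indels == gaps

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(300):
            a = "".join(rng.choice(list("ACGT"), rng.integers(5, 61)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(5, 61)))
            pair = attsite.align_att_pair(a, b, max_gaps=60)
            dist, gaps = oracles.edit_distance_and_min_gaps(a, b)
            assert pair.total_differences == dist
            assert pair.indels == gaps


class TestInferCrossover:
    def test_single_difference_pair_longest_window(self):
        # Binf-1 attL/attR differ only at position 7: the run covering
        # positions 8-35 (28 columns) is the longest conserved window
        sites = DNAJ2["Binf-1"]
        wins = attsite.infer_crossover([sites["attL"], sites["attR"]])
        assert wins[0].length == 28
        assert wins[0].start == 7

    def test_identical_sites_single_full_window(self):
        wins = attsite.infer_crossover(["ACGTACGTAC"] * 3)
        assert len(wins) == 1
        assert (wins[0].start, wins[0].length) == (0, 10)

    def test_all_chaperone_locus_sites_conserve_the_crossover_heptamer(self):
        wins = attsite.infer_crossover(catalog.dnaj2_sites())
        assert any(w.sequence == "GCAAGTT" for w in wins)

    def test_matches_bruteforce_run_scan_on_gapless_sites(self, rng):
        for _ in range(50):
            ref = "".join(rng.choice(list("ACGT"), 40))
            rows = [ref]
            for _ in range(3):
                row = list(ref)
                for p in rng.choice(40, size=4, replace=False):
                    row[p] = rng.choice([c for c in "ACGT" if c != row[p]])
                rows.append("".join(row))
            wins = attsite.infer_crossover(rows, max_gaps=0)
            expected = sorted(
                oracles.conserved_runs(rows), key=lambda t: (-t[1], t[0])
            )
            assert [(w.start, w.length) for w in wins] == expected

    def test_unalignable_sites_error(self):
        with pytest.raises(AlignmentError):
            attsite.infer_crossover(["ACGTACGTACGT", "TTTTTTTTTTTTTTTTTTTTTTT"])

    def test_needs_two_sites(self):
        with pytest.raises(InputError):
            attsite.infer_crossover(["ACGT"])


class TestDeriveAttBattP:
    def test_symmetric_pair(self):
        pair = attsite.align_att_pair("ACGTACGT", "ACGTACGT")
        win = attsite.infer_crossover(["ACGTACGT", "ACGTACGT"])[0]
        s = attsite.derive_attB_attP(pair, win)
        assert s.attB == s.attP == "ACGTACGT"

    def test_string_formula(self):
        pair = attsite.align_att_pair("AAACCCGGGTTT", "TTTCCCGGGAAA")
        win = CrossoverWindow(start=3, length=6, sequence="CCCGGG")
        s = attsite.derive_attB_attP(pair, win)
        assert s.attB == "AAACCCGGGAAA"
        assert s.attP == "TTTCCCGGGTTT"

    def test_round_trip_reconstruction(self):
        sites = DNAJ2["Bb48phi1"]
        pair = attsite.align_att_pair(sites["attL"], sites["attR"])
        win = attsite.infer_crossover([sites["attL"], sites["attR"]])[0]
        s = attsite.derive_attB_attP(pair, win)
        e = win.end
        assert s.attB[:e] + s.attP[e:] == sites["attL"]
        assert s.attP[:e] + s.attB[e:] == sites["attR"]

    def test_crossover_outside_alignment_errors(self):
        pair = attsite.align_att_pair("ACGTACGT", "ACGTACGT")
        with pytest.raises(CrossoverError):
            attsite.derive_attB_attP(
                pair, CrossoverWindow(start=6, length=5, sequence="XXXXX")
            )


class TestExciseIntegrate:
    def test_generator_truth(self):
        genome, truth = synthetic.make_lysogen(1)
        e = truth.expected
        res = attsite.excise(
            genome, e["attL_interval"], e["attR_interval"],
            (e["crossover_offset"], e["crossover_len"]),
        )
        assert res.host == e["host"]
        assert res.virion == e["phage"]
        assert res.attB == e["attB"]
        assert res.attP == e["attP"]

    def test_round_trip_identity(self):
        genome, truth = synthetic.make_lysogen(2)
        e = truth.expected
        res = attsite.excise(
            genome, e["attL_interval"], e["attR_interval"],
            (e["crossover_offset"], e["crossover_len"]),
        )
        back = attsite.integrate(
            res.host, res.attB_interval, res.virion, res.attP_interval,
            (res.crossover_in_attB[0], res.crossover_in_attP[0],
             e["crossover_len"]),
        )
        assert back == genome

    def test_split_marker_gene_restored(self):
        genome, truth = synthetic.make_lysogen(3)
        e = truth.expected
        res = attsite.excise(
            genome, e["attL_interval"], e["attR_interval"],
            (e["crossover_offset"], e["crossover_len"]),
        )
        lo, hi = e["marker_interval"]
        assert translate(res.host[lo - 1 : hi]) == e["marker_protein"]

    def test_base_conservation(self):
        genome, truth = synthetic.make_lysogen(4)
        e = truth.expected
        res = attsite.excise(
            genome, e["attL_interval"], e["attR_interval"],
            (e["crossover_offset"], e["crossover_len"]),
        )
        assert len(res.host) + len(res.virion) == len(genome)

    def test_crossover_mismatch_rejected(self):
        genome, truth = synthetic.make_lysogen(5)
        e = truth.expected
        res = attsite.excise(
            genome, e["attL_interval"], e["attR_interval"],
            (e["crossover_offset"], e["crossover_len"]),
        )
        # single substitution inside the attP crossover
        off = res.crossover_in_attP[0]
        bad = list(res.virion)
        bad[off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad[off]]
        with pytest.raises(CrossoverError):
            attsite.integrate(
                res.host, res.attB_interval, "".join(bad), res.attP_interval,
                (res.crossover_in_attB[0], off, e["crossover_len"]),
            )

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(InputError):
            attsite.excise("ACGT" * 100, (10, 60), (50, 100), (0, 5))

    def test_shared_attB_yields_identical_attL(self, random_dna):
        # integration into two hosts sharing the same attB core
        _, truth = synthetic.make_lysogen(6)
        e = truth.expected
        attB, phage = e["attB"], e["phage"]
        co = (e["crossover_offset"], e["crossover_len"])
        lys = []
        for seed in (101, 102):
            flank = random_dna(300, seed=seed)
            host = flank + attB + flank[::-1]
            iv = (len(flank) + 1, len(flank) + len(attB))
            product = attsite.integrate(host, iv, phage, (1, len(attB)), co)
            lys.append(product[len(flank) : len(flank) + len(attB)])
        assert lys[0] == lys[1] == e["attL"]


class TestRoundTripProperty:
    def test_many_seeded_lysogens(self):
        for seed in range(40):
            genome, truth = synthetic.make_lysogen(
                seed, host_len=1500, phage_len=600
            )
            e = truth.expected
            res = attsite.excise(
                genome, e["attL_interval"], e["attR_interval"],
                (e["crossover_offset"], e["crossover_len"]),
            )
            back = attsite.integrate(
                res.host, res.attB_interval, res.virion, res.attP_interval,
                (res.crossover_in_attB[0], res.crossover_in_attP[0],
                 e["crossover_len"]),
            )
            assert back == genome
            assert len(res.host) + len(res.virion) == len(genome)


class TestSpanStats:
    @pytest.mark.parametrize(
        "name", list(catalog.PROPHAGES)
    )
    def test_published_sizes(self, name):
        rec = catalog.PROPHAGES[name]
        length, _ = attsite.span_stats(rec)
        assert length == catalog.PUBLISHED_SIZES[name]

    def test_reverse_orientation(self):
        rec = ProphageRecord(host_id="x", left=1_246_936, right=1_207_777)
        assert rec.orientation == "reverse"
        assert attsite.span_stats(rec)[0] == 39_160

    def test_gc(self):
        rec = ProphageRecord(host_id="x", left=1, right=4)
        assert attsite.span_stats(rec, "GCGC")[1] == 100.0
        assert attsite.span_stats(rec, "ATAT")[1] == 0.0
        assert attsite.span_stats(rec, "ATGCNN")[1] == 50.0

    def test_bad_coordinates(self):
        with pytest.raises(InputError):
            ProphageRecord(host_id="x", left=0, right=5)


class TestCompareAttAcrossHosts:
    def test_exact_match_first(self):
        ranked = attsite.compare_att_across_hosts(
            "ACGTACGTAC", [("b", "ACGTACGTAG"), ("a", "ACGTACGTAC")]
        )
        assert ranked[0] == ("a", 0)

    def test_constructed_distances(self, random_dna):
        attP = random_dna(35, seed=9)
        near = list(attP)
        near[2] = "A" if near[2] != "A" else "C"
        near[20] = "A" if near[20] != "A" else "C"
        far = list(attP)
        for p in (1, 8, 15, 22, 30):
            far[p] = "A" if far[p] != "A" else "C"
        ranked = attsite.compare_att_across_hosts(
            attP, [("B", "".join(far)), ("A", "".join(near))]
        )
        assert ranked == [("A", 2), ("B", 5)]

    def test_single_difference_proxy_pair(self):
        sites = DNAJ2["Binf-1"]
        ranked = attsite.compare_att_across_hosts(
            sites["attL"], [("self", sites["attR"])]
        )
        assert ranked == [("self", 1)]

    def test_empty_list_errors(self):
        with pytest.raises(InputError):
            attsite.compare_att_across_hosts("ACGTACGT", [])
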