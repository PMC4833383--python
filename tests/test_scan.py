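"""Scanner behaviour: prescreen, brute force vs Boyer-Moore equivalence,
algorithm selection, region restriction, and multi-locus bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirmotif.locusdb import LocusDB, MirnaLocus, RegionSpec, extract_window
from mirmotif.matrix import (
    MatchPolicy,
    ccaat_matrix,
    default_policy,
    expand_exact,
    parse_consensus,
    reverse_complement_str,
)
from mirmotif.scan import (
    choose_algorithm,
    parse_region,
    prescreen,
    scan_all,
    scan_bm,
    scan_brute,
    scan_region,
)
from mirmotif.simulate import generate_background, generate_locus_set


def hit_tuples(hits):
    return [(h.offset, h.strand, h.matched) for h in hits]


class TestPrescreen:
    def test_core_free_text_is_rejected(self, ccaat):
        text = generate_background(2000, seed=3, forbidden_cores=("CCAAT",))
        assert not prescreen(text, ccaat)
        assert scan_brute(text, ccaat) == []  # false guarantees zero hits

    def test_core_containment_in_either_orientation(self, ccaat):
        assert prescreen("xxCCAATxx".replace("x", "G"), ccaat)
        assert prescreen("GGATTGGGG", ccaat)

    def test_no_core_run_passes_unconditionally(self):
        m = parse_consensus("SSSS")
        assert prescreen("AAAA", m)

    def test_negative_prescreen_implies_zero_hits_on_random_strings(self, ccaat, policy):
        rng = np.random.default_rng(11)
        for _ in range(200):
            s = "".join(rng.choice(list("ACGT"), size=60))
            if not prescreen(s, ccaat):
                assert scan_brute(s, ccaat, policy) == []


class TestScanBrute:
    def test_single_forward_hit(self):
        m = parse_consensus("CCAAT")
        hits = scan_brute("TTCCAATT", m, default_policy(strands="forward"))
        assert hit_tuples(hits) == [(2, "+", "CCAAT")]

    def test_tandem_repeat(self):
        m = parse_consensus("CCAAT")
        hits = scan_brute("CCAATCCAAT", m, default_policy(strands="forward"))
        assert [h.offset for h in hits] == [0, 5]

    def test_reverse_orientation_hit(self):
        m = parse_consensus("CCAAT")
        hits = scan_brute("TTATTGGTT", m, default_policy(strands="both"))
        assert hit_tuples(hits) == [(2, "-", "ATTGG")]

    def test_overlapping_hits_all_reported(self):
        m = parse_consensus("AAAA")
        hits = scan_brute("AAAAAA", m, default_policy(strands="forward"))
        assert [h.offset for h in hits] == [0, 1, 2]

    def test_pattern_longer_than_text_is_empty(self):
        m = parse_consensus("CCAATCCAAT")
        assert scan_brute("CCAAT", m) == []

    def test_palindromic_matrix_reports_both_strands_at_one_offset(self):
        m = parse_consensus("CCGG")  # own reverse complement
        hits = scan_brute("ACCGGA", m, default_policy(strands="both"))
        assert hit_tuples(hits) == [(1, "+", "CCGG"), (1, "-", "CCGG")]


class TestBoyerMooreEquivalence:
    def test_anchor_arithmetic_with_offset_core(self, ccaat, policy):
        # CCAAT sits at matrix offset 3: a core occurrence at text position p
        # must trigger a full-window check at p - 3
        text = "G" * 7 + "agcccaatcag".upper() + "G" * 7
        hits = scan_bm(text, ccaat, policy)
        assert hit_tuples(hits) == [(7, "+", "AGCCCAATCAG")]

    def test_65kb_window_agrees_with_brute_force(self, ccaat, policy):
        rng = np.random.default_rng(5)
        text = "".join(rng.choice(list("ACGT"), size=65_000))
        assert scan_bm(text, ccaat, policy) == scan_brute(text, ccaat, policy)

    def test_no_anchor_falls_back_to_brute(self, caplog):
        m = parse_consensus("SSSS")
        pol = MatchPolicy(min_identity=1.0, strands="forward")
        text = "ACCGGCGCA"
        with caplog.at_level("INFO", logger="mirmotif.scan"):
            assert scan_bm(text, m, pol) == scan_brute(text, m, pol)
        assert any("falling back" in r.message for r in caplog.records)

    def test_core_search_agrees_with_biopython_oracle(self):
        """The hand-rolled Boyer-Moore agrees with Bio.SeqUtils.nt_search."""
        from Bio.SeqUtils import nt_search

        from mirmotif.scan import _bm_find_all

        rng = np.random.default_rng(41)
        for _ in range(25):
            text = "".join(rng.choice(list("ACGT"), size=300))
            for pat in ("CCAAT", "ATTGG", "ACG", "GGGG"):
                assert list(_bm_find_all(text, pat)) == nt_search(text, pat)[1:]

    def test_reverse_complement_agrees_with_biopython(self):
        from Bio.Seq import reverse_complement as bio_rc

        rng = np.random.default_rng(43)
        for _ in range(25):
            s = "".join(rng.choice(list("ACGTN"), size=50))
            assert reverse_complement_str(s) == str(bio_rc(s)).upper()

    @given(st.data())
    def test_randomised_equivalence_with_expansion_oracle(self, data):
        iupac = data.draw(
            st.sampled_from(["DVVCCAATSNV", "CCAAT", "RCCAATY", "WWCCGGWW", "ACGTN"])
        )
        strands = data.draw(st.sampled_from(["forward", "reverse", "both"]))
        min_id = data.draw(st.sampled_from([0.5, 0.82, 1.0]))
        text = data.draw(st.text(alphabet="ACGTN", min_size=0, max_size=120))
        m = parse_consensus(iupac)
        pol = MatchPolicy(min_identity=min_id, strands=strands)
        brute = scan_brute(text, m, pol)
        assert scan_bm(text, m, pol) == brute
        # k-mer containment oracle (N-containing slices match nothing)
        fwd = expand_exact(m, MatchPolicy(min_identity=min_id, strands="forward"), cap=200_000)
        rev = expand_exact(
            m.reverse_complement(),
            MatchPolicy(min_identity=min_id, strands="forward"),
            cap=200_000,
        )
        expected = []
        t = text.upper()
        for o in range(max(0, len(t) - m.length + 1)):
            s = t[o : o + m.length]
            if "N" in s:  # N windows are outside the k-mer oracle's domain
                continue
            if strands in ("forward", "both") and s in fwd:
                expected.append((o, "+", s))
            if strands in ("reverse", "both") and s in rev:
                expected.append((o, "-", s))
        assert [h for h in hit_tuples(brute) if "N" not in h[2]] == expected


class TestChooseAlgorithm:
    @pytest.mark.parametrize(
        "length, expected",
        [(20_000, "brute"), (65_000, "boyer_moore"), (32_768, "brute"), (32_769, "boyer_moore")],
    )
    def test_threshold_semantics(self, length, expected):
        assert choose_algorithm(length) == expected

    def test_custom_threshold(self):
        assert choose_algorithm(100, threshold=50) == "boyer_moore"
        with pytest.raises(ValueError):
            choose_algorithm(10, threshold=0)


class TestScanRegion:
    @pytest.fixture()
    def tss_window(self):
        genome, loci, truths = generate_locus_set(
            n_loci=1,
            seed=23,
            up=700,
            down=50,
            planted_sites=[
                ("tss", -401, "+", "agcccaatcag"),
                ("tss", -501, "+", "gggccaatcgg"),
                ("tss", 120, "-", "cggccaatgag"),
            ],
        )
        db = LocusDB.build(genome, loci, up=700, down=50)
        return db.get(loci[0].accession)

    def test_first_base_membership_at_boundaries(self, tss_window, ccaat, policy):
        r = scan_region(tss_window, ccaat, policy, RegionSpec("tss", -500, 500))
        assert sorted(h.rel_tss for h in r.hits) == [-401, 120]  # -501 excluded
        r_all = scan_region(tss_window, ccaat, policy)
        assert sorted(h.rel_tss for h in r_all.hits) == [-501, -401, 120]

    def test_hits_carry_both_anchor_frames(self, tss_window, ccaat, policy):
        r = scan_region(tss_window, ccaat, policy)
        for h in r.hits:
            assert h.rel_pre5 - h.rel_tss == tss_window.tss_offset - tss_window.pre5_offset

    def test_region_clipped_to_window(self, tss_window, ccaat, policy):
        big = scan_region(tss_window, ccaat, policy, RegionSpec("pre5", -10_000, 10_000))
        full = scan_region(tss_window, ccaat, policy)
        assert hit_tuples(big.hits) == hit_tuples(full.hits)

    def test_forced_algorithms_agree(self, tss_window, ccaat, policy):
        a = scan_region(tss_window, ccaat, policy, algorithm="brute")
        b = scan_region(tss_window, ccaat, policy, algorithm="bm")
        assert hit_tuples(a.hits) == hit_tuples(b.hits)

    def test_strand_symmetry_of_window_scans(self, ccaat, policy):
        rng = np.random.default_rng(17)
        text = "".join(rng.choice(list("ACGT"), size=400))
        fwd = scan_brute(text, ccaat, policy)
        rev = scan_brute(reverse_complement_str(text), ccaat, policy)
        L = ccaat.length
        mirrored = sorted(
            (len(text) - L - h.offset, {"+": "-", "-": "+"}[h.strand]) for h in fwd
        )
        assert mirrored == sorted((h.offset, h.strand) for h in rev)

    def test_partition_conservation(self, tss_window, ccaat, policy):
        full = scan_region(tss_window, ccaat, policy)
        n = tss_window.length
        p5 = tss_window.pre5_offset
        cuts = [0, n // 3, 2 * n // 3, n]
        total = 0
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            reg = RegionSpec("pre5", lo - p5, hi - 1 - p5)
            total += scan_region(tss_window, ccaat, policy, reg).n_hits
        assert total == full.n_hits

    def test_parse_region_strings(self):
        assert parse_region("all") is None
        r = parse_region("tss:-500:+500")
        assert (r.anchor, r.from_bp, r.to_bp) == ("tss", -500, 500)
        with pytest.raises(ValueError):
            parse_region("tss:-500")


class TestScanAll:
    def test_bookkeeping_with_tss_less_loci(self, ccaat, policy):
        genome, loci, truths = generate_locus_set(n_loci=10, seed=19, tss_fraction=0.5)
        db = LocusDB.build(genome, loci, up=600, down=50)
        n_missing = sum(l.tss is None for l in loci)
        results, skips = scan_all(db, ccaat, policy, region=RegionSpec("tss", -500, 500))
        assert len(results) == 10 - n_missing
        assert len(skips) == n_missing
        assert all("no TSS" in reason for _, reason in skips)

    def test_total_conservation_and_determinism(self, ccaat, policy, small_locus_set):
        _, genome, loci, truths = small_locus_set
        db = LocusDB.build(genome, loci, up=600, down=50)
        r1, _ = scan_all(db, ccaat, policy)
        r2, _ = scan_all(db, ccaat, policy)
        assert sum(r.n_hits for r in r1) == sum(len(t.planted) for t in truths)
        assert [hit_tuples(a.hits) for a in r1] == [hit_tuples(b.hits) for b in r2]

    def test_accession_selection_preserves_input_order(self, ccaat, policy, small_locus_set):
        _, genome, loci, truths = small_locus_set
        db = LocusDB.build(genome, loci, up=600, down=50)
        pick = [loci[3].accession, loci[1].accession]
        results, _ = scan_all(db, ccaat, policy, accessions=pick)
        assert [r.accession for r in results] == [loci[1].accession, loci[3].accession]
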