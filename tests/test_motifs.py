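import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_match, brute_force_scan
from conftest import region_from
from postdauer.motifs import (Choice, Gap, Literal, MSP_MOTIF, MotifPattern,
                              PatternError, classify_pd_status,
                              compile_pattern, daf3_pattern, match_at,
                              msp_pattern, scan_geneset, scan_region,
                              scan_sequence)

# oracle-verified MSP-motif instances (gap assignments (0,0) and (3,2))
MSP_SHORT = "CTATAAATTAATTTTGCCATAATCT"
MSP_LONG = "CTTTAATTTGGGCAGGTTTTGTCATAAACC"


class TestCompilePattern:
    def test_pure_literal(self):
        p = compile_pattern("GTCTA")
        assert p.blocks == (Literal("GTCTA"),)
        assert p.min_len == p.max_len == 5

    def test_msp_pattern_length_bounds(self):
        p = compile_pattern(MSP_MOTIF)
        assert (p.min_len, p.max_len) == (25, 30)

    @pytest.mark.parametrize("bad", ["CA[X]CTG", "CA[CT", "AN(3,1)A", "A[]A",
                                     "AN(1;2)A", "NACGT", "ACGTN"])
    def test_malformed_or_gap_terminal_patterns_rejected(self, bad):
        with pytest.raises(PatternError):
            compile_pattern(bad)

    def test_both_gap_spellings_and_slash_choices_equivalent(self):
        paren = compile_pattern("CT[AT]TAA[AT]TTN(0,3)[AC]AN(0,2)TTTTGA")
        underscore = compile_pattern("CT[A/T]TAA[A/T]TTN_0-3[A/C]AN_0-2TTTTGA")
        assert paren.blocks == underscore.blocks

    def test_iupac_codes_expand_to_choices(self):
        p = compile_pattern("CASCTG")
        assert p.blocks[1] == Choice(frozenset("CG"))
        assert compile_pattern("AWA").blocks[1] == Choice(frozenset("AT"))

    def test_bare_n_is_single_any_base(self):
        p = compile_pattern("ANA")
        assert p.blocks == (Literal("A"), Gap(1, 1), Literal("A"))
        assert p.min_len == p.max_len == 3


class TestMatchAt:
    def test_exact_literal(self):
        h = match_at(compile_pattern("GTCTA"), "GTCTA", 0)
        assert (h.offset, h.length) == (0, 5)

    @pytest.mark.parametrize("seq,gaps,length", [
        (MSP_SHORT, (0, 0), 25),
        (MSP_LONG, (3, 2), 30),
    ])
    def test_msp_derived_instances(self, seq, gaps, length):
        h = match_at(msp_pattern(), seq, 0)
        assert h is not None
        assert (h.gap_lengths, h.length) == (gaps, length)
        # cross-check with the exhaustive matcher
        assert brute_force_match(msp_pattern(), seq, 0)[0] == (gaps, length)

    def test_n_in_sequence_matches_nothing_even_spacers(self):
        p = compile_pattern("ANA")
        assert match_at(p, "ANA", 0) is None
        assert match_at(p, "ACA", 0) is not None

    def test_leftmost_shortest_gap_assignment(self):
        # A N(0,2) A on "AAA": gaps (0,) at pos 0 beats (1,)
        p = compile_pattern("AN(0,2)A")
        assert match_at(p, "AAA", 0).gap_lengths == (0,)

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            match_at(compile_pattern("A"), "AA", 3)


class TestScanRegion:
    def test_ebox_two_expansions(self):
        hits = scan_region(compile_pattern("CASCTG"),
                           region_from("AACAGCTGACACCTGA"))
        assert [h.offset for h in hits] == [2, 9]

    def test_region_shorter_than_min_len(self):
        assert scan_region(msp_pattern(), region_from("ACGT")) == []

    def test_palindromic_pattern_both_strands_mirror(self):
        seq = "TTTCACGTGAAT"
        hits = scan_region(compile_pattern("CACGTG"), region_from(seq),
                           both_strands=True)
        fwd = [h for h in hits if h.scanned_strand == "forward"]
        rev = [h for h in hits if h.scanned_strand == "revcomp"]
        assert len(fwd) == len(rev) == 1
        # same genomic locus in revcomp coordinates
        assert rev[0].offset == len(seq) - fwd[0].offset - 6

    def test_hits_ordered_and_one_per_start(self):
        hits = scan_region(compile_pattern("AN(0,1)A"), region_from("AAAA"))
        assert [h.offset for h in hits] == [0, 1, 2]
        assert all(h.gap_lengths == (0,) for h in hits)


class TestClassifyPdStatus:
    def test_full_pd_requires_both_components(self, rng):
        spacer = "GGCGGCGGCGGC"
        both = region_from("GTCTA" + spacer + MSP_SHORT, "both")
        daf3_only = region_from("GTCTA" + "A" * 30, "daf3only")
        neither = region_from("N" * 60, "allN")
        status = {s.gene_id: s for s in classify_pd_status(
            [both, daf3_only, neither])}
        assert status["both"].has_full_pd
        assert status["daf3only"].has_daf3 and not status["daf3only"].has_full_pd
        assert not any([status["allN"].has_daf3, status["allN"].has_conserved,
                        status["allN"].has_full_pd])

    def test_duplicate_gene_id_rejected(self):
        r = region_from("ACGTACGT", "dup")
        with pytest.raises(ValueError, match="dup"):
            classify_pd_status([r, r])


class TestScanGeneset:
    def test_zero_patterns_empty_table(self):
        table, sets_ = scan_geneset([], [region_from("ACGT")])
        assert table.empty and sets_ == {}

    def test_hit_counts_and_sets(self):
        ebox = compile_pattern("CASCTG", name="ebox")
        r1 = region_from("TTCACCTGTTCAGCTGTTCACCTGTT", "three")
        r2 = region_from("T" * 26, "zero")
        table, sets_ = scan_geneset([ebox], [r1, r2])
        assert sets_["ebox"] == {"three"}
        assert table.set_index("gene_id").loc["three", "n_hits"] == 3


# -- property-based oracle equivalence ----------------------------------------

@st.composite
def random_pattern(draw):
    n_blocks = draw(st.integers(1, 4))
    blocks = []
    for i in range(n_blocks):
        kind = draw(st.sampled_from(["lit", "choice", "gap"]))
        if kind == "gap" and 0 < i < n_blocks - 1:
            lo = draw(st.integers(0, 2))
            blocks.append(Gap(lo, lo + draw(st.integers(0, 3 - lo))))
        elif kind == "choice":
            blocks.append(Choice(frozenset(draw(
                st.sets(st.sampled_from("ACGT"), min_size=1, max_size=3)))))
        else:
            blocks.append(Literal(draw(st.text("ACGT", min_size=1, max_size=4))))
    return MotifPattern("rand", tuple(blocks))


@given(random_pattern(),
       st.text(alphabet="ACGTN", min_size=0, max_size=60))
@settings(max_examples=300, derandomize=True, deadline=None)
def test_scanner_equals_exhaustive_matcher(pattern, seq):
    got = [(h.offset, h.gap_lengths, h.length)
           for h in scan_sequence(pattern, seq)]
    assert got == brute_force_scan(pattern, seq)


def test_every_hit_reverifies_block_alignment(rng):
    # random sequences; every reported hit re-checked position by position
    p = msp_pattern()
    bases = np.array(list("ACGT"))
    for _ in range(50):
        seq = "".join(rng.choice(bases, size=80))
        for h in scan_sequence(p, seq) + scan_sequence(daf3_pattern(), seq):
            pat = msp_pattern() if h.pattern_name == "msp" else daf3_pattern()
            assert (h.gap_lengths, h.length) in brute_force_match(pat, seq, h.offset)


def test_min_max_len_tightness(rng):
    from postdauer.synth import sample_motif_instance

    p = msp_pattern()
    # some sequence of length min_len matches (all-min gap instance)
    shortest = None
    for s in range(200):
        inst = sample_motif_instance(p, np.random.default_rng(s))
        if len(inst) == p.min_len:
            shortest = inst
            break
    assert shortest is not None and match_at(p, shortest, 0)
    # nothing shorter can match anchored at 0 spanning the whole sequence
    assert match_at(p, shortest[:-1], 0) is None
    # some sequence of length max_len matches anchored at 0 spanning it all
    longest = next(sample_motif_instance(p, np.random.default_rng(s))
                   for s in range(500)
                   if len(sample_motif_instance(p, np.random.default_rng(s)))
                   == p.max_len)
    h = match_at(p, longest, 0)
    assert h is not None and h.length == p.max_len
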