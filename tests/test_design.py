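"""Library design: enumeration, sampling, orientation, oligo assembly."""

import itertools

import pytest

from qtermseq.design import (
    DEGENERATE_CODES,
    DesignError,
    TerminatorDesign,
    TerminatorVariant,
    assemble_in_silico,
    design_half_oligos,
    enumerate_library,
    iter_resolutions,
    reverse_complement,
    reverse_orientation,
    sample_library,
)


def brute_force_stems(pattern):
    """Independent oracle: expand a degenerate pattern exhaustively."""
    choices = [DEGENERATE_CODES.get(c, c) for c in pattern]
    return ["".join(p) for p in itertools.product(*choices)]


class TestEnumeration:
    @pytest.mark.parametrize(
        "pattern",
        ["SNNGCC", "NN", "SSN", "ACGT", "NSNS", "SSSSS"],
    )
    def test_size_and_content_match_brute_force(self, pattern):
        design = TerminatorDesign(stem_pattern_5arm=pattern)
        variants = enumerate_library(design)
        expected = brute_force_stems(pattern)
        assert [v.stem_5arm for v in variants] == sorted(expected)
        n_s, n_n = pattern.count("S"), pattern.count("N")
        assert len(variants) == 2**n_s * 4**n_n

    def test_zero_degenerate_pattern_gives_single_variant(self):
        design = TerminatorDesign(stem_pattern_5arm="GATTACA")
        variants = enumerate_library(design)
        assert len(variants) == 1
        assert variants[0].stem_5arm == "GATTACA"

    def test_single_n_gives_four_alphabetical_variants(self):
        design = TerminatorDesign(stem_pattern_5arm="NGCGCC")
        stems = [v.stem_5arm for v in enumerate_library(design)]
        assert stems == ["AGCGCC", "CGCGCC", "GGCGCC", "TGCGCC"]

    def test_no_duplicates_and_perfect_pairing(self, toy_design):
        variants = enumerate_library(toy_design)
        stems = [v.stem_5arm for v in variants]
        assert len(set(stems)) == len(stems)
        d = toy_design
        for v in variants:
            arm3 = v.forward_seq[
                d.hairpin_start + d.stem_len + len(d.loop_forward) : d.hairpin_end + 1
            ]
            assert arm3 == reverse_complement(v.stem_5arm)

    def test_guard_refuses_oversized_spaces(self):
        design = TerminatorDesign(stem_pattern_5arm="N" * 13)
        with pytest.raises(DesignError, match="sample_library"):
            enumerate_library(design)

    def test_invalid_characters_rejected(self):
        with pytest.raises(DesignError, match="invalid characters"):
            TerminatorDesign(stem_pattern_5arm="SSNXNN")


class TestSampling:
    def test_seed_determinism(self, default_design):
        a = sample_library(default_design, 50, seed=7)
        b = sample_library(default_design, 50, seed=7)
        assert [v.stem_5arm for v in a] == [v.stem_5arm for v in b]

    def test_full_draw_equals_enumeration(self, toy_design):
        sampled = {v.stem_5arm for v in sample_library(toy_design, 32, seed=0)}
        enumerated = {v.stem_5arm for v in enumerate_library(toy_design)}
        assert sampled == enumerated

    def test_overdraw_errors(self):
        design = TerminatorDesign(stem_pattern_5arm="GCCGCC")
        with pytest.raises(DesignError):
            sample_library(design, 2, seed=0)

    def test_samples_are_distinct_and_match_pattern(self, default_design):
        variants = sample_library(default_design, 200, seed=1)
        stems = [v.stem_5arm for v in variants]
        assert len(set(stems)) == 200
        assert all(default_design.matches_pattern(s) for s in stems)


class TestOrientation:
    def test_involution(self, small_library):
        for v in small_library:
            assert reverse_orientation(reverse_orientation(v)) == v

    def test_loop_swap(self, small_library):
        v = small_library[0]
        rv = reverse_orientation(v)
        assert v.orientation_loop == "GAAA"
        assert rv.orientation_loop == "TTTC"
        d = v.design
        loop_at = d.hairpin_start + d.stem_len
        assert rv.forward_seq[loop_at : loop_at + 4] == "TTTC"

    def test_reverse_insert_is_revcomp_of_forward_insert(self, small_library):
        for v in small_library:
            d = v.design
            fwd_insert = v.forward_seq[len(d.prefix) : -len(d.suffix)]
            rev_insert = v.reverse_seq[len(d.prefix) : -len(d.suffix)]
            assert rev_insert == reverse_complement(fwd_insert)

    def test_palindromic_stem_keeps_arms_identical(self):
        # a stem that reverse-complements to itself makes forward and
        # reverse hairpins identical apart from the loop
        design = TerminatorDesign(stem_pattern_5arm="GGCGCC")
        v = enumerate_library(design)[0]
        assert v.stem_5arm == reverse_complement(v.stem_5arm)
        rv = reverse_orientation(v)
        assert rv.stem_5arm == v.stem_5arm


class TestOligoAssembly:
    def test_round_trip_all_variants_of_toy_design(self, toy_design):
        pair = design_half_oligos(toy_design)
        variants = enumerate_library(toy_design)
        resolutions = list(iter_resolutions(toy_design))
        assert len(resolutions) == len(variants) == 32
        for res, v in zip(resolutions, variants):
            assert assemble_in_silico(pair, res) == v.forward_seq

    def test_zero_degenerate_design_reconstructs_exactly(self):
        design = TerminatorDesign(stem_pattern_5arm="GCGGCC")
        pair = design_half_oligos(design)
        variant = enumerate_library(design)[0]
        assert assemble_in_silico(pair, {}) == variant.forward_seq

    def test_half3_is_phosphorylated_and_overlap_is_loop(self, default_design):
        pair = design_half_oligos(default_design)
        assert pair.half3_phosphorylated
        assert pair.anneal_overlap == default_design.loop_forward

    def test_no_overlap_errors(self, toy_design):
        from dataclasses import replace

        pair = design_half_oligos(toy_design)
        broken = replace(pair, anneal_overlap="CCCC")
        res = next(iter_resolutions(toy_design))
        with pytest.raises(DesignError, match="overlap"):
            assemble_in_silico(broken, res)

    def test_incomplete_resolution_errors(self, toy_design):
        pair = design_half_oligos(toy_design)
        with pytest.raises(DesignError, match="missing"):
            assemble_in_silico(pair, {0: "C"})

    def test_resolution_at_fixed_position_errors(self, toy_design):
        pair = design_half_oligos(toy_design)
        res = next(iter_resolutions(toy_design))
        res[3] = "A"  # position 3 of SNNGCC is fixed
        with pytest.raises(DesignError, match="non-degenerate"):
            assemble_in_silico(pair, res)

    def test_degenerate_loop_refused(self):
        design = TerminatorDesign(
            stem_pattern_5arm="SNNGCC", loop_forward="GANA"
        )
        with pytest.raises(DesignError, match="single-strand"):
            design_half_oligos(design)


class TestVariantConstruction:
    def test_stem_must_match_pattern(self, toy_design):
        with pytest.raises(DesignError):
            TerminatorVariant.from_stem(toy_design, "TTTGCC", "x")  # S->T invalid

    def test_forward_seq_layout(self, default_design):
        v = TerminatorVariant.from_stem(
            default_design, "GGACGTACGCCGCC", "t"
        )
        d = default_design
        expected = (
            d.prefix
            + "A" * 8
            + "GGACGTACGCCGCC"
            + "GAAA"
            + reverse_complement("GGACGTACGCCGCC")
            + "T" * 8
            + d.suffix
        )
        assert v.forward_seq == expected
        assert v.forward_seq[d.hairpin_end] == expected[d.hairpin_end]
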