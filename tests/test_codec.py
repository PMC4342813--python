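"""Haplotype codec: parsing, formatting, trimming, masking, distances,
and sequence round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtlineage.codec import (
    DELETION,
    FRAME_CR,
    FRAME_HVS1_2,
    INSERTION,
    SUBSTITUTION,
    DEFAULT_POLICY,
    FrameError,
    Haplotype,
    HaplotypeParseError,
    HotspotPolicy,
    ReadingFrame,
    format_haplotype,
    mask_hotspots,
    pairwise_distance,
    parse_haplotype,
    sequence_to_variants,
    substitution,
    trim_to_frame,
    variants_to_sequence,
)
from tests.conftest import make_random_haplotype

M7C1 = "73G 146C 199C 263G 309.1C 315.1C 489C 523del 524del 16223T 16295T 16362C 16519C"
F1A4A1 = ("73G 152C 249del 263G 309.1C 315.1C 521del 522del 523del 524del "
          "16129A 16172C 16294T 16304C 16362C 16519C")


class TestParseFormat:
    @pytest.mark.parametrize(
        "text, n, n_del, n_ins, n_sub",
        [
            (M7C1, 13, 2, 2, 9),
            ("", 0, 0, 0, 0),
            (F1A4A1, 16, 5, 2, 9),
        ],
    )
    def test_variant_counts(self, text, n, n_del, n_ins, n_sub):
        h = parse_haplotype(text, FRAME_CR)
        kinds = [v.kind for v in h.variants]
        assert len(h.variants) == n
        assert kinds.count(DELETION) == n_del
        assert kinds.count(INSERTION) == n_ins
        assert kinds.count(SUBSTITUTION) == n_sub

    def test_canonical_order_and_case(self):
        h = parse_haplotype("16223t 73g 523DEL", FRAME_CR)
        assert format_haplotype(h) == "73G 523del 16223T"

    def test_printed_order_round_trips(self):
        assert format_haplotype(parse_haplotype(M7C1, FRAME_CR)) == M7C1

    @pytest.mark.parametrize("bad", ["73X73", "abc", "73", ".1C", "309.0C", "73.1del"])
    def test_malformed_token_named_in_error(self, bad):
        with pytest.raises(HaplotypeParseError, match=bad.replace(".", r"\.")):
            parse_haplotype(f"73G {bad}", FRAME_CR)

    def test_out_of_frame_variant_rejected(self):
        with pytest.raises(FrameError):
            parse_haplotype("8000A", FRAME_CR)

    def test_duplicate_variant_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_haplotype("73G 73A", FRAME_CR)

    def test_round_trip_on_random_haplotypes(self, ref):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            h = make_random_haplotype(rng, FRAME_CR, ref, indels=True)
            assert parse_haplotype(format_haplotype(h), FRAME_CR).variants == h.variants

    @given(
        st.lists(
            st.tuples(
                st.integers(16024, 16569),
                st.sampled_from("ACGT"),
            ),
            unique_by=lambda t: t[0],
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_parse_format_identity_property(self, pairs):
        text = " ".join(f"{p}{b}" for p, b in sorted(pairs))
        assert format_haplotype(parse_haplotype(text, FRAME_CR)) == text


class TestTrimAndMask:
    def test_trim_printed_haplotype_to_hvs_frames(self):
        h = parse_haplotype(M7C1, FRAME_CR)
        t = trim_to_frame(h, FRAME_HVS1_2)
        assert format_haplotype(t) == "73G 146C 199C 263G 16223T 16295T 16362C"

    def test_trim_is_idempotent_and_full_frame_is_identity(self, random_haplotype):
        h = random_haplotype(seed=5, indels=True)
        assert trim_to_frame(h, FRAME_CR).variants == h.variants
        once = trim_to_frame(h, FRAME_HVS1_2)
        assert trim_to_frame(once, FRAME_HVS1_2).variants == once.variants

    def test_trim_empty_intersection_errors(self):
        h = parse_haplotype("73G", FRAME_CR)
        with pytest.raises(FrameError):
            trim_to_frame(h, ReadingFrame(((5000, 6000),)))

    def test_hotspot_masking_removes_only_anchor_insertions(self):
        h = parse_haplotype("309.1C 315.1C 16189C 16193.1C", FRAME_CR)
        masked = mask_hotspots(h)
        assert format_haplotype(masked) == "315.1C 16189C"

    def test_masking_leaves_substitutions_and_other_indels(self):
        h = parse_haplotype("309A 523del 573.1C", FRAME_CR)
        assert format_haplotype(mask_hotspots(h)) == "309A 523del"

    def test_empty_haplotype_stable(self):
        h = parse_haplotype("", FRAME_CR)
        assert mask_hotspots(h).variants == ()
        assert trim_to_frame(h, FRAME_HVS1_2).variants == ()


class TestPairwiseDistance:
    def test_examples(self):
        a = parse_haplotype("73G 16223T", FRAME_CR)
        b = parse_haplotype("73G 16362C", FRAME_CR)
        assert pairwise_distance(a, a) == 0
        assert pairwise_distance(a, b) == 2

    def test_hotspot_masked_before_comparison(self):
        a = parse_haplotype("309.1C 73G", FRAME_CR)
        b = parse_haplotype("73G", FRAME_CR)
        assert pairwise_distance(a, b) == 0
        assert pairwise_distance(a, b, HotspotPolicy(frozenset())) == 1

    def test_iupac_heteroplasmy_matches_compatible_base(self):
        a = parse_haplotype("73R", FRAME_CR)
        b = parse_haplotype("73G", FRAME_CR)
        c = parse_haplotype("73C", FRAME_CR)
        assert pairwise_distance(a, b) == 0
        assert pairwise_distance(a, c) == 1

    def test_same_site_conflicting_states_count_one(self):
        a = parse_haplotype("16223T", FRAME_CR)
        b = parse_haplotype("16223C", FRAME_CR)
        assert pairwise_distance(a, b) == 1

    def test_frame_mismatch_errors(self):
        a = parse_haplotype("73G", FRAME_CR)
        b = parse_haplotype("73G", FRAME_HVS1_2)
        with pytest.raises(FrameError):
            pairwise_distance(a, b)

    def test_metric_properties_on_random_triples(self, ref):
        rng = np.random.default_rng(77)
        for _ in range(100):
            x, y, z = (
                make_random_haplotype(rng, FRAME_CR, ref, indels=True)
                for _ in range(3)
            )
            dxy = pairwise_distance(x, y)
            assert dxy == pairwise_distance(y, x)
            assert pairwise_distance(x, x) == 0
            assert dxy <= pairwise_distance(x, z) + pairwise_distance(z, y)


class TestSequenceConversion:
    def test_reference_sequence_gives_no_variants(self, ref):
        seq = variants_to_sequence(Haplotype((), FRAME_CR), ref)
        assert sequence_to_variants(seq, ref, FRAME_CR).variants == ()

    def test_single_substitution(self, ref):
        h = Haplotype((substitution(16223, "T" if ref.base(16223) != "T" else "A"),), FRAME_CR)
        seq = variants_to_sequence(h, ref)
        assert sequence_to_variants(seq, ref, FRAME_CR).variants == h.variants

    def test_ten_substitution_round_trip(self, ref):
        rng = np.random.default_rng(99)
        for _ in range(20):
            h = make_random_haplotype(rng, FRAME_CR, ref, n_variants=(10, 10))
            seq = variants_to_sequence(h, ref)
            back = sequence_to_variants(seq, ref, FRAME_CR)
            assert back.variants == h.variants

    def test_indel_round_trip_is_sequence_faithful_and_canonical(self, ref):
        rng = np.random.default_rng(13)
        for _ in range(30):
            h = make_random_haplotype(rng, FRAME_CR, ref, n_variants=(1, 8), indels=True)
            seq = variants_to_sequence(h, ref)
            h2 = sequence_to_variants(seq, ref, FRAME_CR)
            # same sequence, and the 3'-normalised encoding is a fixed point
            assert variants_to_sequence(h2, ref) == seq
            assert sequence_to_variants(variants_to_sequence(h2, ref), ref, FRAME_CR).variants == h2.variants

    def test_non_iupac_characters_rejected(self, ref):
        with pytest.raises(ValueError, match="non-IUPAC"):
            sequence_to_variants("Z" * len(FRAME_HVS1_2), ref, FRAME_HVS1_2)
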