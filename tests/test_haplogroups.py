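"""Motif-based haplogroup assignment, P1 calling, and frequency tables."""

import numpy as np
import pytest

from mtlineage.codec import (
    FRAME_CR,
    FrameError,
    Haplotype,
    ReadingFrame,
    parse_haplotype,
    substitution,
)
from mtlineage.diversity import PopulationSample
from mtlineage.haplogroups import (
    MotifRule,
    assign_haplogroup,
    classify_P_category,
    haplogroup_frequency_table,
    is_P1,
    load_rules,
    write_rules,
)

M7C1_CR = "73G 146C 199C 263G 16223T 16295T 16362C"
F1A4A1 = ("73G 152C 249del 263G 309.1C 315.1C 521del 522del 523del 524del "
          "16129A 16172C 16294T 16304C 16362C 16519C")


def rule(label, required="", forbidden="", parent=None):
    full = ReadingFrame(((1, 16569),))
    return MotifRule(
        haplogroup=label,
        required=frozenset(parse_haplotype(required, full).variants),
        forbidden=frozenset(parse_haplotype(forbidden, full).variants),
        parent=parent,
    )


class TestAssign:
    def test_root_rule_matches_reference_haplotype(self):
        res = assign_haplogroup(Haplotype((), FRAME_CR), [rule("root")])
        assert res.haplogroup == "root" and res.mismatches == 0

    def test_most_frequent_haplotype_matches_its_rule(self):
        h = parse_haplotype(M7C1_CR, FRAME_CR)
        rules = [rule("root"), rule("M7c1", M7C1_CR), rule("Q1", "16129A 16241G")]
        res = assign_haplogroup(h, rules)
        assert res.haplogroup == "M7c1"
        assert res.mismatches == 0 and res.matched == 7
        assert not res.ambiguous

    def test_equal_sibling_match_is_ambiguous(self):
        h = parse_haplotype("73G", FRAME_CR)
        rules = [rule("A1", "73G 150T"), rule("A2", "73G 200C")]
        res = assign_haplogroup(h, rules)
        assert res.ambiguous and res.mismatches == 1

    def test_tie_broken_toward_least_derived(self):
        h = parse_haplotype("73G", FRAME_CR)
        rules = [rule("twig", "73G 150T 200C"), rule("stem", "73G 150T")]
        assert assign_haplogroup(h, rules).haplogroup == "stem"

    def test_forbidden_hit_disqualifies_despite_full_match(self):
        h = parse_haplotype("73G 150T 263G", FRAME_CR)
        rules = [rule("X", "73G 150T", forbidden="263G"), rule("Y", "73G")]
        assert assign_haplogroup(h, rules).haplogroup == "Y"

    def test_empty_rule_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            assign_haplogroup(Haplotype((), FRAME_CR), [])

    def test_required_outside_frame_not_counted_as_mismatch(self):
        h = parse_haplotype("16357C", ReadingFrame(((16080, 16365),)))
        # HVS-I-only sample cannot be penalised for HVS-II requirements
        res = assign_haplogroup(h, [rule("P1", "73G 263G 16357C")])
        assert res.mismatches == 0


class TestP1:
    def test_minimal_pattern_positive(self):
        h = parse_haplotype("73G 263G 315.1C 16357C", FRAME_CR)
        assert is_P1(h)

    def test_reference_negative(self):
        assert not is_P1(Haplotype((), FRAME_CR))

    def test_printed_f1a4a1_is_not_p1(self):
        assert not is_P1(parse_haplotype(F1A4A1, FRAME_CR))

    def test_hvs1_only_sample_judged_on_covered_positions(self):
        hvs1 = ReadingFrame(((16080, 16180), (16195, 16365)))
        assert is_P1(parse_haplotype("16357C", hvs1))

    def test_frame_without_16357_errors(self):
        h = parse_haplotype("73G", ReadingFrame(((1, 576),)))
        with pytest.raises(FrameError):
            is_P1(h)

    def test_monotone_in_added_variants_and_revoked_without_16357(self):
        base = parse_haplotype("73G 263G 315.1C 16357C", FRAME_CR)
        more = parse_haplotype("73G 152C 263G 315.1C 16357C 16519C", FRAME_CR)
        without = parse_haplotype("73G 263G 315.1C", FRAME_CR)
        assert is_P1(base) and is_P1(more) and not is_P1(without)


class TestPCategories:
    p_rule = None

    def setup_method(self):
        # P membership judged on a motif that does not itself require the
        # P1-defining 16357C, so PxP1 (P but not P1) is representable
        self.p_rule = rule("P", "73G 263G")
        self.motif = frozenset({substitution(16266, "T")})

    def carriers(self):
        return {
            "P1d1": parse_haplotype("73G 263G 315.1C 16266T 16357C", FRAME_CR),
            "P1*": parse_haplotype("73G 263G 315.1C 16357C", FRAME_CR),
            "PxP1": parse_haplotype("73G 263G", FRAME_CR),
            "not-P": parse_haplotype("73G", FRAME_CR),
        }

    def test_partition_matches_definitions(self):
        for want, h in self.carriers().items():
            assert classify_P_category(h, self.motif, self.p_rule) == want

    def test_partition_is_exhaustive_and_disjoint(self, ref):
        from tests.conftest import make_random_haplotype

        rng = np.random.default_rng(31)
        cats = set()
        for _ in range(100):
            h = make_random_haplotype(rng, FRAME_CR, ref, indels=True)
            cats.add(classify_P_category(h, self.motif, self.p_rule))
        assert cats <= {"P1d1", "P1*", "PxP1", "not-P"}

    def test_missing_motif_config_errors(self):
        with pytest.raises(ValueError, match="motif"):
            classify_P_category(self.carriers()["P1*"], frozenset(), self.p_rule)


class TestFrequencyTable:
    def test_single_population_single_haplogroup(self):
        h = parse_haplotype(M7C1_CR, FRAME_CR)
        pop = PopulationSample("ET", [h] * 5, FRAME_CR)
        table = haplogroup_frequency_table([pop], [rule("M7c1", M7C1_CR)])
        assert list(table.pct) == [100.0]
        assert table.n.sum() == 5

    def test_two_populations_disjoint_haplogroups(self):
        a = parse_haplotype("73G 150T", FRAME_CR)
        b = parse_haplotype("263G 16311C", FRAME_CR)
        rules = [rule("A", "73G 150T"), rule("B", "263G 16311C")]
        table = haplogroup_frequency_table(
            [
                PopulationSample("p1", [a] * 3, FRAME_CR),
                PopulationSample("p2", [b] * 4, FRAME_CR),
            ],
            rules,
        )
        pivot = table.pivot(index="Haplogroup", columns="Population", values="n")
        assert pivot.loc["A", "p1"] == 3 and pivot.loc["B", "p2"] == 4
        assert pivot.isna().sum().sum() == 2  # off-diagonal blocks absent

    def test_counts_sum_to_n_and_pct_to_100(self):
        hs = [
            parse_haplotype("73G 150T", FRAME_CR),
            parse_haplotype("263G 16311C", FRAME_CR),
            parse_haplotype("73G 150T", FRAME_CR),
        ]
        pop = PopulationSample("mix", hs, FRAME_CR)
        table = haplogroup_frequency_table(
            [pop], [rule("A", "73G 150T"), rule("B", "263G 16311C")]
        )
        assert table.n.sum() == 3
        assert abs(table.pct.sum() - 100.0) < 0.2


class TestRuleIO:
    def test_round_trip(self, tmp_path):
        rules = [
            rule("P", "73G 263G 16357C"),
            rule("P1", "73G 263G 315.1C 16357C", parent="P"),
            rule("M7c1", M7C1_CR, forbidden="16357C"),
        ]
        path = tmp_path / "rules.tsv"
        write_rules(rules, path)
        back = load_rules(path)
        assert {r.haplogroup: r.required for r in back} == {
            r.haplogroup: r.required for r in rules
        }
        assert back[2].forbidden == rules[2].forbidden

    def test_packaged_example_rules_load(self):
        from importlib import resources

        with resources.as_file(
            resources.files("mtlineage.data") / "example_rules.tsv"
        ) as p:
            rules = load_rules(p)
        assert {"M7c1", "F1a4a1", "P", "P1"} <= {r.haplogroup for r in rules}
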