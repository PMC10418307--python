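import math

import numpy as np
import pytest
from scipy import stats

from allorep.motifs import (
    PatternSets,
    SpecificityPattern,
    assign_clonotypes,
    cluster_origins,
    discover_patterns,
    enumerate_motifs,
    global_templates,
    pattern_set_algebra,
    enrichment_test,
)


def hypergeom_tail_oracle(a, n, b, m):
    """Exact upper-tail sum of the hypergeometric pmf for the 2x2 table."""
    N, K = n + m, a + b
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
        for k in range(a, min(K, n) + 1)
    )


class TestEnumerateMotifs:
    def test_hand_enumeration_with_trim(self):
        motifs = enumerate_motifs(["CASSLGEQYF"], k_range=(4, 4))
        # trimmed region SLGEQ -> 4-mers SLGE, LGEQ
        assert set(motifs) == {"SLGE", "LGEQ"}

    def test_too_short_cdr3_contributes_nothing(self):
        assert enumerate_motifs(["CASSLGYF"], k_range=(4, 4)) == {}

    def test_shared_motif_member_set(self):
        motifs = enumerate_motifs(["CASSLGEQYF", "CATSLGERLFF"], k_range=(4, 4))
        assert motifs["SLGE"] == {"CASSLGEQYF", "CATSLGERLFF"}


class TestEnrichment:
    def test_strong_enrichment_reported(self):
        reported, fold, p = enrichment_test(5, 50, 2, 5000)
        assert reported
        assert fold == pytest.approx(250.0)
        assert p == pytest.approx(hypergeom_tail_oracle(5, 50, 2, 5000), rel=1e-9)

    def test_support_floor_rejects_small_groups(self):
        reported, _, p = enrichment_test(2, 50, 0, 5000)
        assert not reported  # support 2 < 3 regardless of p
        assert p < 1e-3

    def test_zero_reference_uses_pseudocount(self):
        reported, fold, p = enrichment_test(3, 100, 0, 1000)
        assert fold == pytest.approx((3 / 100) / (0.5 / 1000))
        assert reported == (p <= 1e-3)

    def test_matches_exact_hypergeometric_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 200))
            m = int(rng.integers(50, 3000))
            a = int(rng.integers(0, min(n, 30) + 1))
            b = int(rng.integers(0, min(m, 60) + 1))
            _, _, p = enrichment_test(a, n, b, m)
            assert abs(p - hypergeom_tail_oracle(a, n, b, m)) < 1e-10

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(10, 5, 0, 100)


class TestGlobalTemplates:
    def test_hand_constructed_template(self):
        tpl = global_templates(["CASSLGEQYF", "CASSLGDQYF", "CASSLGNQYF"])
        assert len(tpl) == 1
        assert tpl[0].pattern == "CASSLG%QYF"
        assert tpl[0].support == 3

    def test_two_position_difference_gives_no_template(self):
        assert global_templates(["CASSLGEQYF", "CASSMGDQYF", "CASSKGNQYF"]) == []

    def test_wildcard_never_in_untrimmed_positions(self):
        # variants at position 2 (untrimmed) only
        seqs = ["CASSLGEQYF", "CTSSLGEQYF", "CGSSLGEQYF"]
        assert global_templates(seqs) == []

    def test_template_matches_its_members(self):
        tpl = global_templates(["CASSLGEQYF", "CASSLGDQYF", "CASSLGNQYF"])[0]
        assert all(tpl.matches(m) for m in tpl.members)
        assert not tpl.matches("CASSLGEQYFF")


def P(pattern, kind="local", members=()):
    return SpecificityPattern(kind, pattern, frozenset(members))


class TestPatternSetAlgebra:
    def test_shared_patterns_excluded_from_both(self):
        sets = pattern_set_algebra([P("AAAA"), P("BBBB"), P("CCCC")],
                                   [P("BBBB"), P("DDDD")])
        assert {p.pattern for p in sets.shared_di} == {"BBBB"}
        assert {p.pattern for p in sets.direct_exclusive} == {"AAAA", "CCCC"}
        assert {p.pattern for p in sets.indirect_exclusive} == {"DDDD"}

    def test_unstim_subtraction_flag(self):
        sets = pattern_set_algebra([P("AAAA"), P("BBBB"), P("CCCC")],
                                   [P("BBBB"), P("DDDD")],
                                   [P("CCCC")], subtract_unstim=True)
        assert {p.pattern for p in sets.direct_exclusive} == {"AAAA"}
        off = pattern_set_algebra([P("AAAA"), P("BBBB"), P("CCCC")],
                                  [P("BBBB"), P("DDDD")],
                                  [P("CCCC")], subtract_unstim=False)
        assert {p.pattern for p in off.direct_exclusive} == {"AAAA", "CCCC"}

    def test_disjoint_inputs_pass_through(self):
        sets = pattern_set_algebra([P("AAAA")], [P("BBBB")])
        assert sets.direct_exclusive == sets.direct
        assert sets.indirect_exclusive == sets.indirect
        assert sets.shared_di == []

    def test_exclusive_sets_are_disjoint_and_accounting_holds(self):
        direct = [P(x) for x in ("AAAA", "BBBB", "CCCC", "EEEE")]
        indirect = [P(x) for x in ("BBBB", "DDDD")]
        unstim = [P(x) for x in ("CCCC",)]
        sets = pattern_set_algebra(direct, indirect, unstim, True)
        dx = {p.identity() for p in sets.direct_exclusive}
        ix = {p.identity() for p in sets.indirect_exclusive}
        assert dx & ix == set()
        n_unstim_only = len(
            {p.identity() for p in direct} & {p.identity() for p in unstim}
            - {p.identity() for p in sets.shared_di}
        )
        assert len(direct) == len(sets.direct_exclusive) + len(sets.shared_di) + n_unstim_only


class TestAssignClonotypes:
    def make_sets(self):
        return PatternSets(
            direct=[], indirect=[], unstim=[],
            direct_exclusive=[P("SLGE", members=("CASSLGEQYF",))],
            indirect_exclusive=[P("DAGG", members=("CASSDAGGYEQYF",))],
        )

    def test_single_arm_match_labeled(self):
        labels = assign_clonotypes(["CASSLGEQYF"], self.make_sets())
        assert labels == {"CASSLGEQYF": "direct"}

    def test_double_match_is_ambiguous_and_excluded(self):
        labels = assign_clonotypes(["CASSLGEDAGGYF"], self.make_sets())
        assert labels == {}

    def test_no_match_unlabeled(self):
        assert assign_clonotypes(["CATTTTTTTF"], self.make_sets()) == {}


class TestClusterOrigins:
    def test_origin_counts_and_histogram_conservation(self):
        patterns = [
            SpecificityPattern("local", "AAAA", frozenset({"c1", "c2"}),
                               source_conditions=frozenset({"BlL0", "VacDC"})),
            SpecificityPattern("local", "BBBB", frozenset({"c3"}),
                               source_conditions=frozenset({"BlL0"})),
            SpecificityPattern("local", "CCCC", frozenset({"c4"}),
                               source_conditions=frozenset({"BlL0", "VacDC", "Trans"})),
        ]
        per_pattern, hist = cluster_origins(patterns)
        assert per_pattern[("local", "AAAA")] == 2
        assert per_pattern[("local", "BBBB")] == 1
        assert hist == {1: 1, 2: 1, 3: 1}
        assert sum(hist.values()) == len(patterns)


def test_discovered_pattern_members_always_match_their_pattern():
    rng = np.random.default_rng(7)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    background = ["CASS" + "".join(rng.choice(list(aa), 8)) + "QYF" for _ in range(400)]
    motif = "WQKV"
    carriers = ["CASS" + motif + "".join(rng.choice(list(aa), 4)) + "QYF" for _ in range(6)]
    patterns = discover_patterns(carriers + background[:40], background)
    assert any(p.pattern == motif for p in patterns if p.kind == "local")
    for p in patterns:
        for member in p.members:
            assert p.matches(member) or (p.kind == "local" and p.pattern in member)
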