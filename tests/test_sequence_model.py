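"""Pool bookkeeping, viability rules, and enumeration of supersequences."""

import pytest

from noahgen import Supersequence, check_viability, enumerate_viable, magnetization_trace
from noahgen.errors import UnknownModule
from noahgen.module_library import MagnetizationPool, ModuleCategory
from noahgen.sequence_model import PoolState, brute_force_viable

BULK = MagnetizationPool.BULK_1H
C13 = MagnetizationPool.C13_BOUND_1H
N15 = MagnetizationPool.N15_BOUND_1H


class TestMagnetizationTrace:
    def test_hsqc_leaves_bulk_untouched(self):
        trace = magnetization_trace(Supersequence(("S", "C")))
        after_s = trace[0]
        assert after_s[BULK] is PoolState.INTACT
        assert after_s[C13] is PoolState.CONSUMED

    def test_homonuclear_excites_everything(self):
        trace = magnetization_trace(Supersequence(("C", "S")))
        after_c = trace[0]
        assert after_c[C13] is PoolState.CONSUMED
        assert after_c[N15] is PoolState.CONSUMED
        assert after_c[BULK] is PoolState.PARTIAL  # COSY-type partial survival

    def test_hmbc_preserves_satellites_partially_consumes_bulk(self):
        trace = magnetization_trace(Supersequence(("B", "S")))
        after_b = trace[0]
        assert after_b[BULK] is PoolState.PARTIAL
        assert after_b[C13] is PoolState.INTACT
        assert after_b[N15] is PoolState.INTACT

    def test_empty_sequence_gives_empty_trace(self):
        assert magnetization_trace(Supersequence(())) == []

    def test_unknown_module_raises(self):
        with pytest.raises(UnknownModule):
            magnetization_trace(Supersequence(("S", "QQ")))


class TestCheckViability:
    @pytest.mark.parametrize("mods", [("S", "C"), ("B", "S", "C"),
                                      ("M", "S", "C"), ("Sp", "Cc"),
                                      ("B", "M", "S", "C"),
                                      ("B", "St", "S", "C", "N")])
    def test_known_good_orderings(self, mods):
        assert check_viability(Supersequence(mods)).viable

    def test_cs_rejected_with_pool_diagnostic(self):
        verdict = check_viability(Supersequence(("C", "S")))
        assert not verdict.viable
        assert any(d.pool is C13 for d in verdict.fatal_diagnostics())

    def test_sbc_rejected_hmbc_must_lead(self):
        verdict = check_viability(Supersequence(("S", "B", "C")))
        assert not verdict.viable
        assert any("lead" in d.message for d in verdict.fatal_diagnostics())

    def test_length_cap(self):
        six = ("B", "M", "St", "S", "C", "N")
        verdict = check_viability(Supersequence(six))
        assert not verdict.viable
        assert check_viability(Supersequence(six[:5])).viable

    def test_single_module_too_short(self):
        assert not check_viability(Supersequence(("S",))).viable

    def test_repeated_module_rejected(self):
        assert not check_viability(Supersequence(("S", "S"))).viable

    def test_n15_must_precede_c13(self):
        assert check_viability(Supersequence(("M", "S"))).viable
        assert not check_viability(Supersequence(("S", "M"))).viable

    def test_tolerated_loss_is_a_nonfatal_diagnostic(self):
        verdict = check_viability(Supersequence(("B", "S", "C")))
        notes = [d for d in verdict.diagnostics if not d.fatal]
        assert any(d.pool is BULK for d in notes)

    def test_second_c13_module_only_after_relay(self):
        assert check_viability(Supersequence(("St", "S"))).viable
        assert not check_viability(Supersequence(("S", "Sp"))).viable

    def test_noe_type_module_cannot_lead_a_homonuclear_pair(self):
        assert check_viability(Supersequence(("C", "N"))).viable
        assert not check_viability(Supersequence(("N", "C"))).viable


class TestEnumerateViable:
    def test_single_module_registry_is_empty(self, registry):
        assert enumerate_viable(registry=registry.restricted(["S"])) == []

    def test_two_module_registry_brute_force(self, registry):
        sub = registry.restricted(["S", "C"])
        seqs = enumerate_viable(2, 2, registry=sub)
        assert [s.modules for s in seqs] == [("S", "C")]

    def test_oracle_equivalence_on_subregistry(self, registry):
        sub = registry.restricted(["B", "M", "S", "C", "N", "P"])
        fast = {s.modules for s in enumerate_viable(registry=sub)}
        oracle = {s.modules for s in brute_force_viable(2, 5, registry=sub)}
        assert fast == oracle

    def test_no_duplicates_and_length_bounds(self, registry):
        seqs = enumerate_viable()
        mods = [s.modules for s in seqs]
        assert len(mods) == len(set(mods))
        assert all(2 <= len(m) <= 5 for m in mods)

    def test_count_stable_and_documented(self):
        # the count the shipped registry and rules yield (see docs/methods.md)
        assert len(enumerate_viable()) == 1112

    def test_monotonicity_under_registry_restriction(self, registry):
        full = len(enumerate_viable(registry=registry))
        for dropped in ["B", "M", "C", "P"]:
            keep = [a for a in registry.abbreviations() if a != dropped]
            smaller = len(enumerate_viable(registry=registry.restricted(keep)))
            assert smaller <= full

    def test_prefix_property(self, registry):
        viable = {s.modules for s in enumerate_viable()}
        for mods in viable:
            for k in range(2, len(mods)):
                assert check_viability(Supersequence(mods[:k])).viable

    def test_category_ordering(self, registry):
        het = (ModuleCategory.HET_13C, ModuleCategory.HET_15N)
        for s in enumerate_viable():
            cats = [registry.get(a).category for a in s.modules]
            seen_h1 = False
            for c in cats:
                if c not in het:
                    seen_h1 = True
                else:
                    assert not seen_h1, f"{s}: heteronuclear after homonuclear"
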