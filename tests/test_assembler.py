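"""Collation, phase merging, nine-section assembly, and the footer contract."""

import pytest

from noahgen import (
    GeneratorMetadata,
    Supersequence,
    assemble,
    collate_parameters,
    merge_phase_cycles,
    parse_footer,
    render_annotations,
    resolve,
)
from noahgen.assembler import SECTION_MARKERS, PulseProgramText
from noahgen.errors import (
    MalformedFooter,
    MissingAnnotation,
    ParameterConflict,
    PhaseIndexConflict,
)
from noahgen.module_library import PhaseCycle
from noahgen.variant_resolver import ResolvedSequence

from conftest import FIXED_TS, make_module, param


def _resolved(*mods):
    return ResolvedSequence(resolved_modules=tuple(mods), glue_blocks=(),
                            options=frozenset())


class TestCollateParameters:
    def test_shared_delay_merges_to_single_entry(self):
        """Sp and Cc both standardize on cnst2-style shared slots; identical
        definitions collapse to one table entry."""
        resolved = resolve(Supersequence(("Sp", "Cc")))
        params = collate_parameters(resolved)
        tokens = [p.token for p in params]
        assert tokens.count("p1") == 1
        assert tokens.count("p16") == 1
        assert tokens.count("cnst2") == 1

    def test_conflicting_definitions_raise_naming_both_modules(self):
        a = make_module("X1", parameters=[param("CONSTANT", 2, "145", "J one")])
        b = make_module("X2", parameters=[param("CONSTANT", 2, "160", "J two")])
        with pytest.raises(ParameterConflict, match="X1.*X2"):
            collate_parameters(_resolved(a, b))

    def test_single_module_table_unchanged(self):
        mod = make_module("X1", parameters=[param("PULSE", 1), param("DELAY", 16)])
        out = collate_parameters(_resolved(mod))
        assert {p.key for p in out} == {p.key for p in mod.parameters}


class TestMergePhaseCycles:
    def test_hmbc_cycles_survive_merge(self, registry):
        resolved = resolve(Supersequence(("B", "S", "C")))
        table = merge_phase_cycles(resolved)
        by_index = {c.index: c for c in table.cycles}
        assert by_index[1].steps == ("x", "-x")
        assert by_index[2].steps == ("x", "x", "-x", "-x")
        assert table.receiver_indices[0] == 17  # HMBC receiver first

    def test_disjoint_indices_union(self):
        a = make_module("X1", phase_cycles=[PhaseCycle(1, ("x", "-x")),
                                            PhaseCycle(20, ("x",), True)])
        b = make_module("X2", phase_cycles=[PhaseCycle(2, ("y", "-y")),
                                            PhaseCycle(21, ("x",), True)])
        table = merge_phase_cycles(_resolved(a, b))
        assert [c.index for c in table.cycles] == [1, 2, 20, 21]
        assert table.receiver_indices == (20, 21)

    def test_same_index_different_steps_conflicts(self):
        a = make_module("X1", phase_cycles=[PhaseCycle(1, ("x", "-x")),
                                            PhaseCycle(20, ("x",), True)])
        b = make_module("X2", phase_cycles=[PhaseCycle(1, ("y", "-y")),
                                            PhaseCycle(21, ("x",), True)])
        with pytest.raises(PhaseIndexConflict, match="ph1"):
            merge_phase_cycles(_resolved(a, b))

    def test_module_without_receiver_rejected(self):
        a = make_module("X1", phase_cycles=[PhaseCycle(1, ("x", "-x"))])
        with pytest.raises(PhaseIndexConflict, match="receiver"):
            merge_phase_cycles(_resolved(a))


class TestAssemble:
    def test_footer_encodes_metadata(self, build):
        text = build(["Sp", "Cc"], version="2.1.0")
        meta, au = parse_footer(text.render())
        assert meta.module_list == ("Sp", "Cc")
        assert meta.version == "2.1.0"
        assert meta.timestamp == FIXED_TS
        assert au == ("noah_hsqc", "noah_clipcosy")

    def test_byte_determinism(self, build):
        a = build(["B", "S", "C"]).render()
        b = build(["B", "S", "C"]).render()
        assert a == b
        assert a.encode() == b.encode()

    def test_hmbc_purge_pulse_follows_zz_filter(self, build):
        """The 13C 90 purge pulse sits between the zz-filter and the LPJF."""
        rendered = build(["B", "S", "C"]).render()
        filt = rendered.index("zz-filter: return 13C-bound 1H to +z")
        purge = rendered.index("added 13C 90 pulse after the zz-filter")
        lpjf = rendered.index("low-pass J-filter")
        assert filt < purge < lpjf

    def test_section_order_and_presence(self, build):
        rendered = build(["M", "S", "C"]).render()
        positions = [rendered.index(SECTION_MARKERS[n]) for n in range(1, 10)]
        assert positions == sorted(positions)

    def test_main_block_tokens_are_defined(self, build):
        """No p#/d#/cnst#/gpz#/ph# token in the main block lacks a
        definition in the delay/parameter/phase/gradient sections."""
        from noahgen.lint import lint
        report = lint(build(["B", "M", "S", "C"]))
        assert not [e for e in report.errors if e.code == "UNDEFINED_SYMBOL"]

    def test_metadata_module_list_must_match(self):
        resolved = resolve(Supersequence(("S", "C")))
        meta = GeneratorMetadata("2.1.0", FIXED_TS, ("B",))
        with pytest.raises(ValueError):
            assemble(resolved, meta)

    def test_parse_inverts_render(self, build):
        text = build(["B", "S", "C"])
        again = PulseProgramText.parse(text.render())
        assert again.footer == text.footer
        assert again.main == text.main


class TestRenderAnnotations:
    def test_hmbc_gradient_table_gives_five_comment_lines(self):
        resolved = resolve(Supersequence(("B", "S"), developer_mode=True))
        # restrict to the HMBC module alone for the per-module count
        solo = ResolvedSequence((resolved.resolved_modules[0],), (), frozenset())
        grads, _, _ = render_annotations(solo)
        assert len(grads) == 5
        assert any("+/-40.2%" in g for g in grads)

    def test_module_without_shaped_pulses_gives_empty_wavemaker(self):
        mod = make_module("X1", parameters=[param("PULSE", 1)])
        _, wvm, _ = render_annotations(_resolved(mod))
        assert wvm == ()

    def test_missing_ased_comment_raises_in_strict_mode(self):
        mod = make_module("X1", parameters=[param("PULSE", 1, comment="")])
        with pytest.raises(MissingAnnotation):
            render_annotations(_resolved(mod), strict=True)
        _, _, ased = render_annotations(_resolved(mod), strict=False)
        assert not any(ln.startswith(";p1:") for ln in ased)


class TestParseFooter:
    def test_round_trip(self, build):
        for mods in [("S", "C"), ("B", "S", "C"), ("B", "M", "St", "S", "C")]:
            text = build(list(mods), version="2.1.0")
            meta, au = parse_footer(text.render())
            assert meta.module_list == mods
            assert meta.version == "2.1.0"

    def test_au_program_for_hsqc_slot(self, build):
        _, au = parse_footer(build(["B", "S", "C"]).render())
        assert au[1] == "noah_hsqc"

    @pytest.mark.parametrize("key", ["MODULES", "AUPROG", "VERSION", "TIMESTAMP"])
    def test_deleting_any_footer_line_is_malformed(self, build, key):
        rendered = build(["S", "C"]).render()
        mutated = "\n".join(ln for ln in rendered.splitlines()
                            if not ln.startswith(f";{key}: "))
        with pytest.raises(MalformedFooter):
            parse_footer(mutated)

    def test_mismatched_module_and_au_lists(self, build):
        rendered = build(["S", "C"]).render()
        mutated = rendered.replace(";AUPROG: noah_hsqc,noah_cosy",
                                   ";AUPROG: noah_hsqc")
        with pytest.raises(MalformedFooter):
            parse_footer(mutated)
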