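"""Render a resolved supersequence into Bruker-dialect pulse program text.

The generated document has nine sections in fixed order:

1. module-specific delay definitions (``define delay DC_HSQC1`` + relation)
2. standardized parameter definitions (coupling-constant defaults, t1
   increment relations)
3. the main pulse sequence: recovery delay, then module bodies joined by
   glue blocks
4. looping / t1-incrementation / echo-antiecho commands
5. phase cycle definitions (``ph1=0 2``)
6. gradient comments readable by TopSpin's ``gppp`` script
7. WaveMaker directives for shaped pulses
8. one-line parameter descriptions shown in the ``ased`` setup screen
9. footer: per-module AU programs, module list, generator version and
   timestamp (machine-parseable for the processing pipeline)

Serialization is byte-deterministic given fixed metadata.  TopSpin's ``mc``
macro syntax is approximated by an explicit loop tail; the dialect is pinned
by the accompanying linter, not by TopSpin itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import (
    MalformedFooter,
    MissingAnnotation,
    ParameterConflict,
    PhaseIndexConflict,
    SectionOrderError,
)
from .module_library import (
    CouplingConstants,
    DEFAULT_COUPLINGS,
    GradientSpec,
    Parameter,
    ParameterKind,
    PhaseCycle,
    ShapedPulse,
)
from .variant_resolver import GlueBlock, GlueKind, ResolvedSequence

SECTION_MARKERS = {
    1: ";--- (1) module-specific delays ---",
    2: ";--- (2) parameter definitions ---",
    3: ";--- (3) pulse sequence ---",
    4: ";--- (4) looping and incrementation ---",
    5: ";--- (5) phase cycles ---",
    6: ";--- (6) gradients (gppp) ---",
    7: ";--- (7) shaped pulses (wavemaker) ---",
    8: ";--- (8) parameter descriptions (ased) ---",
    9: ";--- (9) processing and provenance ---",
}

# assembler-owned elements shared by all supersequences
_RECOVERY_BLOCK = [
    ";--- recovery delay ---",
    "#ifdef PRESAT",
    "  4u pl9:f1",
    "  d1 cw:f1",
    "  4u do:f1",
    "  4u pl1:f1",
    "#else",
    "  d1",
    "#endif",
]
_PURGE_GLUE = [
    "  (p1 ph0):f1",
    "  p16:gp30",
    "  d16",
]
_ASAP_GLUE = [
    "  (p50:sp50 ph0):f1",
    "  p16:gp30",
    "  d16",
]
_D1 = Parameter(ParameterKind.DELAY, 1, "", "recovery (relaxation) delay")
_P50 = Parameter(ParameterKind.PULSE, 50, "",
                 "ASAP isotropic mixing (DIPSI-2) total duration")
_GP30 = GradientSpec(30, 33.0, 1.0, "SMSQ10.100")
_SP50 = ShapedPulse("sp50", "p50", "asap_mix: DIPSI-2 supercycle (40 ms)")


@dataclass(frozen=True)
class GeneratorMetadata:
    version: str
    timestamp: str  # ISO-8601 UTC, e.g. 2022-01-20T00:00:00Z
    module_list: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "module_list", tuple(self.module_list))


@dataclass(frozen=True)
class PhaseTable:
    cycles: tuple[PhaseCycle, ...]          # sorted by index, unique
    receiver_indices: tuple[int, ...]       # one per module, in module order


@dataclass(frozen=True)
class PulseProgramText:
    """The structured nine-section output document."""

    header: tuple[str, ...]
    local_delays: tuple[str, ...]
    param_defs: tuple[str, ...]
    main: tuple[str, ...]
    increments: tuple[str, ...]
    phases: tuple[str, ...]
    gradient_comments: tuple[str, ...]
    wavemaker: tuple[str, ...]
    ased: tuple[str, ...]
    footer: tuple[str, ...]

    _SECTION_FIELDS = ("local_delays", "param_defs", "main", "increments",
                      "phases", "gradient_comments", "wavemaker", "ased",
                      "footer")

    def render(self) -> str:
        lines = list(self.header)
        for n, name in enumerate(self._SECTION_FIELDS, start=1):
            lines.append("")
            lines.append(SECTION_MARKERS[n])
            lines.extend(getattr(self, name))
        return "\n".join(lines) + "\n"

    @classmethod
    def parse(cls, text: str) -> "PulseProgramText":
        """Split rendered text back into sections (raises on missing/misordered
        markers)."""
        lines = text.splitlines()
        positions = []
        for n in range(1, 10):
            try:
                positions.append(lines.index(SECTION_MARKERS[n]))
            except ValueError:
                raise SectionOrderError(
                    f"section marker {SECTION_MARKERS[n]!r} missing"
                ) from None
        if positions != sorted(positions):
            raise SectionOrderError("section markers out of order")

        def chunk(a, b):
            part = lines[a + 1:b]
            while part and part[-1] == "":
                part.pop()
            while part and part[0] == "":
                part.pop(0)
            return tuple(part)

        header = tuple(ln for ln in lines[:positions[0]] if ln != "")
        bounds = positions + [len(lines)]
        parts = [chunk(bounds[i], bounds[i + 1]) for i in range(9)]
        return cls(header, *parts)


# ---------------------------------------------------------------------------
# collation
# ---------------------------------------------------------------------------

def collate_parameters(resolved: ResolvedSequence,
                       extra: Sequence[tuple[str, Parameter]] = (),
                       ) -> list[Parameter]:
    """Merge per-module parameter tables into one program-wide table.

    Identical duplicates (same slot, definition and description) collapse to
    one entry; the same slot with differing content is a curation error and
    raises :class:`ParameterConflict` naming both modules.
    """
    table: dict[tuple, tuple[Parameter, str]] = {}
    sources = [(m.abbreviation, p)
               for m in resolved.resolved_modules for p in m.parameters]
    sources += list(extra)
    for owner, p in sources:
        if p.key in table:
            existing, first_owner = table[p.key]
            if (existing.definition, existing.ased_comment) != (p.definition,
                                                                p.ased_comment):
                raise ParameterConflict(
                    f"{p.token} defined differently by {first_owner} and {owner}")
        else:
            table[p.key] = (p, owner)
    order = {k: i for i, k in enumerate(ParameterKind)}
    return sorted((p for p, _ in table.values()),
                  key=lambda p: (order[p.kind], str(p.index_or_name)))


def merge_phase_cycles(resolved: ResolvedSequence) -> PhaseTable:
    """Program-wide phase table plus the per-module receiver cycle list."""
    cycles: dict[int, tuple[PhaseCycle, str]] = {}
    receivers = []
    for m in resolved.resolved_modules:
        recs = [c for c in m.phase_cycles if c.is_receiver]
        if len(recs) != 1:
            raise PhaseIndexConflict(
                f"module {m.abbreviation} must declare exactly one receiver "
                f"cycle, found {len(recs)}")
        receivers.append(recs[0].index)
        for c in m.phase_cycles:
            if c.index in cycles:
                existing, owner = cycles[c.index]
                if (existing.steps, existing.is_receiver) != (c.steps, c.is_receiver):
                    raise PhaseIndexConflict(
                        f"ph{c.index} defined differently by {owner} and "
                        f"{m.abbreviation}")
            else:
                cycles[c.index] = (c, m.abbreviation)
    ordered = tuple(c for _, (c, _) in sorted(cycles.items()))
    return PhaseTable(ordered, tuple(receivers))


def collate_gradients(resolved: ResolvedSequence,
                      extra: Sequence[GradientSpec] = ()) -> list[GradientSpec]:
    table: dict[int, tuple[GradientSpec, str]] = {}
    sources = [(m.abbreviation, g)
               for m in resolved.resolved_modules for g in m.gradients]
    sources += [("(assembler)", g) for g in extra]
    for owner, g in sources:
        if g.index in table:
            existing, first_owner = table[g.index]
            if existing != g:
                raise ParameterConflict(
                    f"gpz{g.index} defined differently by {first_owner} and {owner}")
        else:
            table[g.index] = (g, owner)
    return [g for _, (g, _) in sorted(table.items())]


def _collate_shaped(resolved: ResolvedSequence,
                    extra: Sequence[ShapedPulse] = ()) -> list[ShapedPulse]:
    table: dict[str, ShapedPulse] = {}
    for m in resolved.resolved_modules:
        for s in m.shaped_pulses:
            if s.name in table and table[s.name] != s:
                raise ParameterConflict(f"{s.name} has conflicting directives")
            table[s.name] = s
    for s in extra:
        table.setdefault(s.name, s)
    return [table[k] for k in sorted(table, key=lambda n: int(n[2:]))]


# ---------------------------------------------------------------------------
# section rendering
# ---------------------------------------------------------------------------

def render_annotations(resolved: ResolvedSequence, strict: bool = True,
                       ) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Sections 6-8: gradient comments, WaveMaker directives, ased comments."""
    glue_kinds = {g.kind for g in resolved.glue_blocks}
    extra_grads = [_GP30] if resolved.glue_blocks else []
    extra_shapes = [_SP50] if GlueKind.ASAP_MIXING in glue_kinds else []
    extra_params = _assembler_parameters(resolved)

    gradients = collate_gradients(resolved, extra_grads)
    grad_lines = tuple(
        f";gpz{g.index}: {'+/-' if g.echo_antiecho else ''}{g.amplitude:g}% "
        f"({g.duration:g} ms, {g.shape})"
        for g in gradients)

    shaped = _collate_shaped(resolved, extra_shapes)
    wvm_lines = tuple(f";{s.name}:wvm:{s.directive}" for s in shaped)

    params = collate_parameters(resolved, extra_params)
    ased_lines = []
    for p in params:
        if not p.ased_comment:
            if strict:
                raise MissingAnnotation(f"parameter {p.token} has no description")
            continue
        ased_lines.append(f";{p.token}: {p.ased_comment}")
    return grad_lines, wvm_lines, tuple(ased_lines)


def _assembler_parameters(resolved: ResolvedSequence) -> list[tuple[str, Parameter]]:
    extra = [("(assembler)", _D1)]
    if any(g.kind is GlueKind.ASAP_MIXING for g in resolved.glue_blocks):
        extra.append(("(assembler)", _P50))
    return extra


def _coupling_defaults(params: Sequence[Parameter],
                       couplings: CouplingConstants) -> list[str]:
    values = {2: couplings.one_bond_JCH, 4: couplings.one_bond_JNH,
              13: couplings.long_range_JCH}
    lines = []
    for p in params:
        if p.kind is ParameterKind.CONSTANT and p.index_or_name in values:
            lines.append(f'"cnst{p.index_or_name}={values[p.index_or_name]:g}"')
    return lines


def assemble(resolved: ResolvedSequence, metadata: GeneratorMetadata,
             couplings: CouplingConstants = DEFAULT_COUPLINGS) -> PulseProgramText:
    """Construct the full nine-section pulse program document."""
    mods = resolved.resolved_modules
    n = len(mods)
    if tuple(metadata.module_list) != resolved.abbreviations:
        raise ValueError("metadata module list does not match resolved sequence")

    params = collate_parameters(resolved, _assembler_parameters(resolved))
    phase_table = merge_phase_cycles(resolved)
    grad_lines, wvm_lines, ased_lines = render_annotations(resolved)

    # (a) header
    name = f"noah{n}-" + "".join(resolved.abbreviations)
    flag_syms = sorted(f for f in resolved.options if f != "FORCEASAP")
    header = [
        f"; {name}",
        f"; NOAH-{n} supersequence: "
        + " + ".join(m.display_name for m in mods),
        "; generated offline; pool-checked"
        + (" (developer mode)" if resolved.developer_mode else ""),
        ";zgoptns: " + (" ".join(f"-D{f}" for f in flag_syms) if flag_syms
                        else "(none requested)"),
    ]

    # (1) local delays
    local = []
    for p in params:
        if p.kind is ParameterKind.LOCAL_DELAY:
            local.append(f"define delay {p.token}")
            local.append(f'"{p.token}={p.definition}"')

    # (2) standardized parameter definitions
    pdefs = _coupling_defaults(params, couplings)
    indirect_mods = [(i, m) for i, m in enumerate(mods) if m.indirect]
    for k, (_, m) in enumerate(indirect_mods, start=1):
        pdefs.append(f'"in{k}=inf{k}/2"')

    # (3) main block
    glue_by_pos = {g.position: g for g in resolved.glue_blocks}
    main = ["1 ze", "2 30m"]
    main += _RECOVERY_BLOCK
    for i, m in enumerate(mods):
        if i in glue_by_pos:
            g = glue_by_pos[i]
            if g.kind is GlueKind.ASAP_MIXING:
                main.append(f";--- glue before module {i + 1}: ASAP isotropic mixing ---")
                main += _ASAP_GLUE
            elif g.kind is GlueKind.PURGE_PULSE_PFG:
                main.append(f";--- glue before module {i + 1}: purge pulse + PFG ---")
                main += _PURGE_GLUE
        label = m.display_name if m.variant_label is None else (
            f"{m.display_name}, variant {m.variant_label}")
        main.append(f";=== module {i + 1} of {n}: {m.abbreviation} ({label}) ===")
        main += [ln for ln in m.body_template.rstrip("\n").splitlines()
                 if ln.strip() != ""]

    # (4) incrementation / echo-antiecho
    inc = []
    ea_counter = 0
    for k, (i, m) in enumerate(indirect_mods, start=1):
        inc.append(f"; module {i + 1} ({m.abbreviation}): t1 incrementation")
        t1 = m.indirect.t1_delay
        step = f"in{k}*cnst37" if m.k_scaling else f"in{k}"
        inc.append("#ifdef NUS")
        inc.append(f"; {t1} follows the sampled increment list (sidecar schedule file)")
        inc.append("#else")
        inc.append(f'  "{t1}={t1}+{step}"')
        inc.append("#endif")
        if m.sapphire:
            inc.append(f'  "{t1}={t1}+in{k}/cnst38" ; SAPPHIRE zero-point advance')
        if m.indirect.echo_antiecho:
            ea_counter += 1
            inc.append(f"  igrad EA{ea_counter} "
                       f"; invert gpz{m.indirect.ea_gradient} between FIDs "
                       "(echo-antiecho)")
    inc.append("  lo to 2 times td1")
    inc.append("exit")

    # (5) phases
    phase_lines = [c.render() for c in phase_table.cycles]
    phase_lines.append("; receiver cycles by module: "
                       + ", ".join(f"ph{ix}" for ix in phase_table.receiver_indices))

    # (9) footer
    footer = [
        ";MODULES: " + ",".join(resolved.abbreviations),
        ";AUPROG: " + ",".join(m.au_program for m in mods),
        f";VERSION: {metadata.version}",
        f";TIMESTAMP: {metadata.timestamp}",
    ]

    return PulseProgramText(
        header=tuple(header),
        local_delays=tuple(local),
        param_defs=tuple(pdefs),
        main=tuple(main),
        increments=tuple(inc),
        phases=tuple(phase_lines),
        gradient_comments=grad_lines,
        wavemaker=wvm_lines,
        ased=ased_lines,
        footer=tuple(footer),
    )


# ---------------------------------------------------------------------------
# footer parsing (the contract consumed by the splitx-style processing chain)
# ---------------------------------------------------------------------------

def parse_footer(text: str) -> tuple[GeneratorMetadata, tuple[str, ...]]:
    """Recover metadata and the per-module AU program list from program text.

    Accepts any conforming text (not only our own output): the four footer
    lines must appear, in order, after the last section marker.
    """
    if isinstance(text, PulseProgramText):
        lines = list(text.footer)
    else:
        lines = text.splitlines()
    fields = {}
    order = []
    for ln in lines:
        for key in ("MODULES", "AUPROG", "VERSION", "TIMESTAMP"):
            if ln.startswith(f";{key}: "):
                if key in fields:
                    raise MalformedFooter(f"duplicate ;{key}: line")
                fields[key] = ln[len(key) + 3:].strip()
                order.append(key)
    expected = ["MODULES", "AUPROG", "VERSION", "TIMESTAMP"]
    if sorted(fields) != sorted(expected):
        missing = set(expected) - set(fields)
        raise MalformedFooter(f"footer lines missing: {sorted(missing)}")
    if order != expected:
        raise MalformedFooter(f"footer lines out of order: {order}")
    modules = tuple(m for m in fields["MODULES"].split(",") if m)
    au = tuple(a for a in fields["AUPROG"].split(",") if a)
    if len(modules) != len(au):
        raise MalformedFooter("module and AU program lists differ in length")
    meta = GeneratorMetadata(version=fields["VERSION"],
                             timestamp=fields["TIMESTAMP"],
                             module_list=modules)
    return meta, au
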