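"""Static validation of generated pulse-program text.

The generated dialect is simple enough to check mechanically: every symbol
used in the pulse sequence must be declared in the appropriate section,
nothing may be declared twice, conditional-compilation guards must balance
and name known acquisition flags, the nine sections must appear in order,
and the machine-readable footer must parse.  The linter reports; it never
throws.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .assembler import SECTION_MARKERS, parse_footer
from .errors import MalformedFooter
from .flags_nus import FLAGS

_TRACKED = re.compile(
    r"\b(p\d+|d\d+|cnst\d+|gpz\d+|gp\d+|ph\d+|sp\d+|D[CNH]_[A-Z0-9]+)\b")
_DEFINE_DELAY = re.compile(r"^define delay (D[CNH]_[A-Z0-9]+)\s*$")
_RELATION = re.compile(r'^\s*"([A-Za-z][A-Za-z0-9_]*)=(.*)"')
_PHASE_DEF = re.compile(r"^(ph\d+)=")
_GRAD_COMMENT = re.compile(r"^;(gpz\d+):")
_WVM = re.compile(r"^;(sp\d+):wvm:")
_ASED = re.compile(r"^;((?:p|d|cnst|gpz|gpnam|sp)\d+|D[CNH]_[A-Z0-9]+): ")


@dataclass(frozen=True)
class LintMessage:
    line: int       # 1-based line number in the rendered text
    code: str
    message: str


@dataclass
class LintReport:
    errors: list[LintMessage] = field(default_factory=list)
    warnings: list[LintMessage] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors

    def error(self, line: int, code: str, message: str) -> None:
        self.errors.append(LintMessage(line, code, message))

    def warn(self, line: int, code: str, message: str) -> None:
        self.warnings.append(LintMessage(line, code, message))


def _norm(token: str) -> str:
    """gp# and gpz# address the same gradient; normalize to gpz#."""
    m = re.fullmatch(r"gp(\d+)", token)
    return f"gpz{m.group(1)}" if m else token


def _code_part(line: str) -> str:
    return line.split(";", 1)[0]


def lint(text) -> LintReport:
    """Validate pulse program text; returns a report, never raises."""
    if hasattr(text, "render"):
        text = text.render()
    report = LintReport()
    lines = text.splitlines()

    # section structure
    marker_pos: dict[int, int] = {}
    for i, ln in enumerate(lines):
        for n, marker in SECTION_MARKERS.items():
            if ln == marker:
                if n in marker_pos:
                    report.error(i + 1, "SECTION_ORDER",
                                 f"section marker ({n}) duplicated")
                else:
                    marker_pos[n] = i
    missing = [n for n in range(1, 10) if n not in marker_pos]
    for n in missing:
        report.error(len(lines), "SECTION_ORDER", f"section marker ({n}) missing")
    present = [n for n in sorted(marker_pos)]
    if [marker_pos[n] for n in present] != sorted(marker_pos[n] for n in present):
        report.error(1, "SECTION_ORDER", "section markers out of order")

    # footer contract
    try:
        parse_footer(text)
    except MalformedFooter as e:
        report.error(len(lines), "FOOTER", str(e))

    if missing:
        return report  # symbol analysis needs the section map

    def section_of(i: int) -> int:
        sec = 0
        for n in range(1, 10):
            if i > marker_pos[n]:
                sec = n
        return sec

    defs: dict[tuple[str, str], int] = {}      # (category, token) -> first line
    refs: dict[str, int] = {}                  # token -> first referencing line

    def define(category: str, token: str, i: int) -> None:
        key = (category, _norm(token))
        if key in defs:
            report.error(i + 1, "DUPLICATE_DEF",
                         f"{token} already defined at line {defs[key] + 1} "
                         f"({category})")
        else:
            defs[key] = i

    def refer(token: str, i: int) -> None:
        refs.setdefault(_norm(token), i)

    guard_stack: list[tuple[int, str]] = []
    for i, ln in enumerate(lines):
        sec = section_of(i)
        stripped = ln.strip()

        if stripped.startswith("#ifdef"):
            parts = stripped.split()
            sym = parts[1] if len(parts) > 1 else ""
            if sym not in FLAGS:
                report.error(i + 1, "UNKNOWN_FLAG_SYMBOL",
                             f"#ifdef guard uses unknown symbol {sym!r}")
            guard_stack.append((i, sym))
            continue
        if stripped.startswith("#else"):
            if not guard_stack:
                report.error(i + 1, "GUARD_UNBALANCED", "#else without #ifdef")
            continue
        if stripped.startswith("#endif"):
            if guard_stack:
                guard_stack.pop()
            else:
                report.error(i + 1, "GUARD_UNBALANCED", "#endif without #ifdef")
            continue

        if sec == 1:
            m = _DEFINE_DELAY.match(ln)
            if m:
                define("delay", m.group(1), i)
                continue
            m = _RELATION.match(ln)
            if m:
                define("relation", m.group(1), i)
                for t in _TRACKED.findall(m.group(2)):
                    refer(t, i)
                continue
        elif sec == 2:
            m = _RELATION.match(ln)
            if m:
                if _TRACKED.fullmatch(m.group(1)):
                    define("relation", m.group(1), i)
                for t in _TRACKED.findall(m.group(2)):
                    refer(t, i)
                continue
        elif sec in (3, 4):
            for t in _TRACKED.findall(_code_part(ln)):
                refer(t, i)
        elif sec == 5:
            m = _PHASE_DEF.match(ln)
            if m:
                define("phase", m.group(1), i)
        elif sec == 6:
            m = _GRAD_COMMENT.match(ln)
            if m:
                define("gradient", m.group(1), i)
        elif sec == 7:
            m = _WVM.match(ln)
            if m:
                define("wavemaker", m.group(1), i)
        elif sec == 8:
            m = _ASED.match(ln)
            if m:
                define("ased", m.group(1), i)

    for i, sym in guard_stack:
        report.error(i + 1, "GUARD_UNBALANCED", f"#ifdef {sym} never closed")

    defined_tokens = {tok for (_, tok) in defs}
    for tok, i in sorted(refs.items(), key=lambda kv: kv[1]):
        if tok not in defined_tokens:
            report.error(i + 1, "UNDEFINED_SYMBOL",
                         f"{tok} is referenced but never defined")
            continue
        # named delays must have an explicit `define delay` declaration;
        # a bare relation is not enough for the compiler
        if tok.startswith("D") and ("delay", tok) not in defs:
            report.error(i + 1, "UNDEFINED_SYMBOL",
                         f"{tok} has no `define delay` declaration")
        if tok.startswith("ph") and ("phase", tok) not in defs:
            report.error(i + 1, "UNDEFINED_SYMBOL",
                         f"{tok} has no phase cycle definition")
        if tok.startswith("gpz") and ("gradient", tok) not in defs:
            report.error(i + 1, "UNDEFINED_SYMBOL",
                         f"{tok} has no gradient table entry")

    warned: set[str] = set()
    for (category, tok), i in sorted(defs.items(), key=lambda kv: kv[1]):
        if (tok not in refs and tok not in warned
                and category in ("delay", "phase", "gradient", "ased")):
            warned.add(tok)
            report.warn(i + 1, "UNUSED_DEF",
                        f"{tok} is defined but never used")
    return report
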