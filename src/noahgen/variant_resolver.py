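"""Context-sensitive variant resolution and inter-module glue.

Three decisions depend on *which other modules* a supersequence contains:

* which form of the HMBC zz-filter to use (retain 13C-bound and/or
  15N-bound 1H magnetization only if a later module needs it);
* whether a seHSQC module carries its ZIP element (only if bulk
  magnetization must survive for a later module);
* what goes between modules (ASAP mixing before the first homonuclear
  module when an HMBC leads; otherwise a purge pulse + PFG).

All three are pure functions of the registry pool declarations, so new
modules participate without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import HMBCNotPresent, NotSeHSQC
from .module_library import (
    MagnetizationPool,
    ModuleCategory,
    ModuleDefinition,
    Registry,
    default_registry,
)
from .sequence_model import Supersequence

# variant labels of the shipped zz-HMBC, keyed by
# (needs 13C-bound later?, needs 15N-bound later?)
HMBC_VARIANT_TABLE = {
    (False, False): "C_HMBC_A",
    (True, False): "C_HMBC_C",
    (False, True): "C_HMBC_N",
    (True, True): "C_HMBC_CN",
}

# Option flag that forces ASAP mixing even before a NOESY module.
FORCE_ASAP_OPTION = "FORCEASAP"


class GlueKind(str, Enum):
    PURGE_PULSE_PFG = "PURGE_PULSE_PFG"
    ASAP_MIXING = "ASAP_MIXING"
    NONE = "NONE"


@dataclass(frozen=True)
class GlueBlock:
    position: int        # glue precedes the module at this (0-based) index
    kind: GlueKind


@dataclass(frozen=True)
class ResolvedSequence:
    resolved_modules: tuple[ModuleDefinition, ...]
    glue_blocks: tuple[GlueBlock, ...]
    options: frozenset[str]
    developer_mode: bool = False

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(m.abbreviation for m in self.resolved_modules)


def _later_needs(seq: Supersequence, position: int, pool: MagnetizationPool,
                 registry: Registry) -> bool:
    return any(pool in registry.get(a).pools_required
               for a in seq.modules[position + 1:])


def resolve_hmbc_filter(seq: Supersequence,
                        registry: Optional[Registry] = None) -> str:
    """Choose the zz-filter form for the HMBC module in ``seq``.

    The filter retains exactly the heteronucleus-bound pools that some later
    module requires.  In developer mode an explicit override wins verbatim
    (validity of the label is still checked against the registry).
    """
    registry = registry or default_registry()
    positions = [i for i, a in enumerate(seq.modules)
                 if registry.get(a).slot == "hmbc"]
    if not positions:
        raise HMBCNotPresent(f"no HMBC module in {seq}")
    pos = positions[0]
    abbr = seq.modules[pos]
    if seq.developer_mode and abbr in seq.variant_overrides:
        label = seq.variant_overrides[abbr]
        registry.get(abbr).with_variant(label)  # raises UnknownVariant
        return label
    needs_c = _later_needs(seq, pos, MagnetizationPool.C13_BOUND_1H, registry)
    needs_n = _later_needs(seq, pos, MagnetizationPool.N15_BOUND_1H, registry)
    return HMBC_VARIANT_TABLE[(needs_c, needs_n)]


def resolve_zip(seq: Supersequence, position: int,
                registry: Optional[Registry] = None) -> bool:
    """True iff the seHSQC at ``position`` (0-based) keeps its ZIP element.

    The ZIP element protects bulk magnetization for later modules; when
    nothing after the seHSQC draws on the bulk pool it is omitted to
    maximize sensitivity.
    """
    registry = registry or default_registry()
    mod = registry.get(seq.modules[position])
    if not mod.zip_block:
        raise NotSeHSQC(f"module {mod.abbreviation} at position {position} "
                        "has no ZIP element")
    return _later_needs(seq, position, MagnetizationPool.BULK_1H, registry)


def resolve_glue(seq: Supersequence,
                 registry: Optional[Registry] = None) -> tuple[GlueBlock, ...]:
    """Glue blocks at each module boundary (positions 1 .. n-1).

    ASAP mixing goes immediately before the first homonuclear module when an
    HMBC module precedes it, replenishing the bulk pool the HMBC has drawn
    on; it is suppressed when that module is a NOESY (mixing would perturb
    NOE buildup) unless the FORCEASAP option is set.  Every other boundary
    receives a purge pulse + PFG.
    """
    registry = registry or default_registry()
    mods = [registry.get(a) for a in seq.modules]
    blocks = []
    hmbc_before = False
    asap_done = False
    for i, m in enumerate(mods):
        if i > 0:
            kind = GlueKind.PURGE_PULSE_PFG
            if (m.category is ModuleCategory.HOMONUCLEAR and hmbc_before
                    and not asap_done):
                suppress = (m.abbreviation == "N"
                            and FORCE_ASAP_OPTION not in seq.options)
                if not suppress:
                    kind = GlueKind.ASAP_MIXING
                asap_done = True
            blocks.append(GlueBlock(i, kind))
        if m.slot == "hmbc":
            hmbc_before = True
    return tuple(blocks)


def resolve(seq: Supersequence,
            registry: Optional[Registry] = None) -> ResolvedSequence:
    """Full resolution: variants chosen, ZIP decided, glue placed."""
    registry = registry or default_registry()
    resolved = []
    for i, abbr in enumerate(seq.modules):
        mod = registry.get(abbr)
        if mod.slot == "hmbc" and mod.variants:
            mod = mod.with_variant(resolve_hmbc_filter(seq, registry))
        elif seq.developer_mode and abbr in seq.variant_overrides:
            mod = mod.with_variant(seq.variant_overrides[abbr])
        if mod.zip_block:
            block = mod.zip_block.rstrip("\n") if resolve_zip(seq, i, registry) else ""
            body = mod.body_template.replace("{{ZIP}}", block)
            body = "\n".join(ln for ln in body.splitlines() if ln.strip() != "")
            mod = _replace_body(mod, body)
        resolved.append(mod)
    return ResolvedSequence(
        resolved_modules=tuple(resolved),
        glue_blocks=resolve_glue(seq, registry),
        options=seq.options,
        developer_mode=seq.developer_mode,
    )


def _replace_body(mod: ModuleDefinition, body: str) -> ModuleDefinition:
    from dataclasses import replace
    return replace(mod, body_template=body)
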