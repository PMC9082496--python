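"""Magnetization-pool bookkeeping and supersequence viability.

A NOAH supersequence shares one recovery delay between all of its modules,
so each module must draw only on magnetization that earlier modules left
behind.  The registry declares, per module, which proton pools it requires,
which it consumes, and which it preserves; a pool appearing in both the
consumed and preserved sets survives *partially* — later use is possible
but costs sensitivity (a "tolerated loss", e.g. a COSY running on the bulk
magnetization an HMBC has already excited, acceptable because the COSY is
far more sensitive than the HMBC).

Viability combines this pool trace with a small number of structural
ordering rules that the pool algebra cannot express (HMBC leads the
supersequence; 15N modules precede 13C modules; at most two 13C modules and
at most two bulk-pool modules).  Everything is derived from the registry so
that adding a module is purely a data change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import permutations
from typing import Iterator, Mapping, Optional

from .errors import UnknownModule
from .module_library import (
    MagnetizationPool,
    ModuleCategory,
    ModuleDefinition,
    Registry,
    default_registry,
)

MIN_MODULES = 2
MAX_MODULES = 5

# Bulk-observing slots ("h1"): at most this many homonuclear + pure shift
# modules per supersequence.
MAX_H1_MODULES = 2
MAX_C13_MODULES = 2


class PoolState(str, Enum):
    INTACT = "INTACT"
    PARTIAL = "PARTIAL"
    CONSUMED = "CONSUMED"


@dataclass(frozen=True)
class ToleratedLossRule:
    """Documented case where reuse of an already-drawn pool is acceptable."""

    earlier: str      # category or abbreviation of the earlier module
    later: str        # category of the later module
    pool: MagnetizationPool
    rationale: str


# The fixed, documented tolerated-loss set.  These are *descriptive*: the
# machine-readable form is the partial-survival (consumed & preserved)
# declaration in the registry, from which the pool trace below works.
TOLERATED_LOSS_RULES: tuple[ToleratedLossRule, ...] = (
    ToleratedLossRule(
        "HMBC", "HOMONUCLEAR/PURESHIFT_2DJ", MagnetizationPool.BULK_1H,
        "homonuclear modules after an HMBC tolerate bulk losses: their "
        "intrinsic sensitivity far exceeds the HMBC's, and ASAP mixing "
        "replenishes the pool"),
    ToleratedLossRule(
        "HOMONUCLEAR", "HOMONUCLEAR/PURESHIFT_2DJ", MagnetizationPool.BULK_1H,
        "a second bulk-observing module may follow a COSY/TOCSY-type module "
        "(e.g. COSY then NOESY) with tolerated partial loss"),
    ToleratedLossRule(
        "St", "HET_13C", MagnetizationPool.C13_BOUND_1H,
        "the HSQC-TOCSY relay redistributes 13C-bound magnetization, so one "
        "further 13C module may follow it"),
)


@dataclass(frozen=True)
class Supersequence:
    """An ordered, option-decorated module selection."""

    modules: tuple[str, ...]
    options: frozenset[str] = frozenset()
    developer_mode: bool = False
    variant_overrides: Mapping[str, str] = field(default_factory=dict)

    def __init__(self, modules, options=(), developer_mode=False,
                 variant_overrides=None):
        object.__setattr__(self, "modules", tuple(modules))
        object.__setattr__(self, "options", frozenset(options))
        object.__setattr__(self, "developer_mode", bool(developer_mode))
        object.__setattr__(self, "variant_overrides", dict(variant_overrides or {}))

    @classmethod
    def parse(cls, spec: str, **kw) -> "Supersequence":
        """Build from a comma-separated module string such as ``"B,S,C"``."""
        return cls(tuple(s.strip() for s in spec.split(",") if s.strip()), **kw)

    def __str__(self) -> str:
        return ",".join(self.modules)


@dataclass(frozen=True)
class Diagnostic:
    position: int                     # 0-based module index the problem is at
    pool: Optional[MagnetizationPool]
    message: str
    fatal: bool = True


@dataclass(frozen=True)
class ViabilityVerdict:
    viable: bool
    diagnostics: tuple[Diagnostic, ...]

    def fatal_diagnostics(self) -> tuple[Diagnostic, ...]:
        return tuple(d for d in self.diagnostics if d.fatal)


def _definitions(seq: Supersequence, registry: Registry) -> list[ModuleDefinition]:
    return [registry.get(a) for a in seq.modules]


def magnetization_trace(seq: Supersequence,
                        registry: Optional[Registry] = None,
                        ) -> list[dict[MagnetizationPool, PoolState]]:
    """Pool states after each module (index i = state after modules 0..i).

    A consumed pool drops to PARTIAL if the module declares partial
    survival for it, otherwise to CONSUMED; pools the module neither
    consumes nor preserves (nonselective excitation) are consumed outright.
    """
    registry = registry or default_registry()
    states = {p: PoolState.INTACT for p in MagnetizationPool}
    trace = []
    for mod in _definitions(seq, registry):
        for pool in MagnetizationPool:
            if pool in mod.pools_partial:
                if states[pool] is PoolState.INTACT:
                    states[pool] = PoolState.PARTIAL
            elif pool in mod.pools_consumed or pool not in mod.pools_preserved:
                states[pool] = PoolState.CONSUMED
            # else: fully preserved, state unchanged
        trace.append(dict(states))
    return trace


def check_viability(seq: Supersequence,
                    registry: Optional[Registry] = None) -> ViabilityVerdict:
    """Pool-trace plus structural-rule viability check.

    The verdict ignores ``developer_mode`` (the build pipeline decides
    whether fatal diagnostics block generation or are demoted to warnings).
    """
    registry = registry or default_registry()
    mods = _definitions(seq, registry)
    diags: list[Diagnostic] = []

    n = len(mods)
    if not MIN_MODULES <= n <= MAX_MODULES:
        diags.append(Diagnostic(
            max(n - 1, 0), None,
            f"supersequence length {n} outside the supported range "
            f"{MIN_MODULES}-{MAX_MODULES}"))

    seen: set[str] = set()
    for i, m in enumerate(mods):
        if m.abbreviation in seen:
            diags.append(Diagnostic(
                i, None, f"module {m.abbreviation} appears more than once"))
        seen.add(m.abbreviation)

    for i, m in enumerate(mods):
        if m.slot == "hmbc" and i != 0:
            diags.append(Diagnostic(
                i, None,
                f"HMBC module {m.abbreviation} must lead the supersequence "
                "(its zz-filter is designed for equilibrium magnetization)"))

    last_n15 = max((i for i, m in enumerate(mods) if m.slot == "n15"), default=-1)
    first_c13 = min((i for i, m in enumerate(mods) if m.slot == "c13"), default=n)
    if last_n15 > first_c13:
        diags.append(Diagnostic(
            last_n15, None,
            "15N modules must precede 13C modules (the less sensitive "
            "experiment runs on the fresher magnetization)"))

    n_c13 = sum(m.slot == "c13" for m in mods)
    if n_c13 > MAX_C13_MODULES:
        diags.append(Diagnostic(
            n - 1, None, f"at most {MAX_C13_MODULES} 13C modules allowed"))
    n_h1 = sum(m.slot == "h1" for m in mods)
    if n_h1 > MAX_H1_MODULES:
        diags.append(Diagnostic(
            n - 1, None,
            f"at most {MAX_H1_MODULES} bulk-pool (homonuclear/pure shift) "
            "modules allowed"))

    # pool trace: a module whose required pool is already consumed is fatal;
    # a PARTIAL pool is a tolerated loss (warning only).
    states = {p: PoolState.INTACT for p in MagnetizationPool}
    for i, m in enumerate(mods):
        for pool in sorted(m.pools_required):
            if states[pool] is PoolState.CONSUMED:
                diags.append(Diagnostic(
                    i, pool,
                    f"module {m.abbreviation} needs {pool.value}, which an "
                    "earlier module has consumed"))
            elif states[pool] is PoolState.PARTIAL:
                diags.append(Diagnostic(
                    i, pool,
                    f"module {m.abbreviation} draws on partially depleted "
                    f"{pool.value} (tolerated loss)", fatal=False))
        for pool in MagnetizationPool:
            if pool in m.pools_partial:
                if states[pool] is PoolState.INTACT:
                    states[pool] = PoolState.PARTIAL
            elif pool in m.pools_consumed or pool not in m.pools_preserved:
                states[pool] = PoolState.CONSUMED

    fatal = [d for d in diags if d.fatal]
    return ViabilityVerdict(viable=not fatal, diagnostics=tuple(diags))


def enumerate_viable(min_len: int = MIN_MODULES, max_len: int = MAX_MODULES,
                     registry: Optional[Registry] = None,
                     ) -> list[Supersequence]:
    """All viable supersequences, by prefix-pruned depth-first search.

    Every structural rule and the pool trace are monotone under extension,
    so a non-viable prefix of length >= 2 can never be completed to a viable
    sequence and its subtree is pruned.  (The brute-force oracle over all
    ordered selections is kept in the test suite.)
    """
    if not MIN_MODULES <= min_len <= max_len <= MAX_MODULES:
        raise ValueError(f"need {MIN_MODULES} <= min_len <= max_len <= {MAX_MODULES}")
    registry = registry or default_registry()
    abbrs = registry.abbreviations()
    out: list[Supersequence] = []

    def extend(prefix: tuple[str, ...]) -> None:
        for a in abbrs:
            if a in prefix:
                continue
            cand = prefix + (a,)
            seq = Supersequence(cand)
            if len(cand) >= 2 and not check_viability(seq, registry).viable:
                continue
            if len(cand) >= min_len:
                out.append(seq)
            if len(cand) < max_len:
                extend(cand)

    extend(())
    return out


def brute_force_viable(min_len: int, max_len: int,
                       registry: Optional[Registry] = None,
                       ) -> list[Supersequence]:
    """Oracle: filter all ordered module selections by check_viability."""
    registry = registry or default_registry()
    abbrs = registry.abbreviations()
    out = []
    for k in range(min_len, max_len + 1):
        for combo in permutations(abbrs, k):
            seq = Supersequence(combo)
            if check_viability(seq, registry).viable:
                out.append(seq)
    return out
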