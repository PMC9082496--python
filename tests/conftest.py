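import pytest

from noahgen import build_program, default_registry
from noahgen.module_library import (
    MagnetizationPool,
    ModuleCategory,
    ModuleDefinition,
    Parameter,
    ParameterKind,
    PhaseCycle,
)

FIXED_TS = "2022-01-20T00:00:00Z"


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def build():
    """Build a pulse program with a pinned timestamp (determinism in tests)."""

    def _build(modules, **kw):
        kw.setdefault("timestamp", FIXED_TS)
        text, _ = build_program(modules, **kw)
        return text

    return _build


def make_module(abbr, *, parameters=(), phase_cycles=None, body="  goscnp ph18",
                category=ModuleCategory.HOMONUCLEAR, slot="h1",
                au_program="noah_test", shaped_pulses=()):
    """Minimal synthetic module definition for collation/merge fixtures."""
    if phase_cycles is None:
        phase_cycles = (PhaseCycle(18, ("x", "-x"), is_receiver=True),)
    return ModuleDefinition(
        abbreviation=abbr,
        display_name=f"fixture {abbr}",
        category=category,
        slot=slot,
        pools_required=frozenset({MagnetizationPool.BULK_1H}),
        pools_consumed=frozenset({MagnetizationPool.BULK_1H}),
        pools_preserved=frozenset(),
        parameters=tuple(parameters),
        phase_cycles=tuple(phase_cycles),
        gradients=(),
        body_template=body,
        au_program=au_program,
        shaped_pulses=tuple(shaped_pulses),
    )


def param(kind, idx, definition="", comment="a comment"):
    return Parameter(ParameterKind[kind], idx, definition, comment)
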