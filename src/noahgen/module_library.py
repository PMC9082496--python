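"""NOAH module registry: definitions, parameter tables and timing formulas.

A NOAH supersequence concatenates several 2D NMR "modules" (HMBC, HSQC,
COSY, ...) behind a single recovery delay.  Each module is described by a
structured data file shipped with the package (``registry/*.yaml``) holding
its parameter, phase-cycle and gradient tables together with the pulse
program body for the module itself.  This module loads those files into
immutable definition objects and provides the small amount of physics that
is computed rather than tabulated: INEPT/HMBC transfer delays from scalar
coupling constants, and coherence-transfer-pathway (CTP) gradient amplitude
ratios from gyromagnetic ratios.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional

import yaml

from .errors import NonPositiveCoupling, UnknownModule, UnknownVariant

# Gyromagnetic ratios in rad s^-1 T^-1.  gamma(15N) is negative.
GAMMA_H = 26.7522128e7
GAMMA_C = 6.728284e7
GAMMA_N = -2.7126e7


class MagnetizationPool(str, Enum):
    """The three proton magnetization reservoirs a NOAH module can draw on.

    BULK_1H is the magnetization of protons bound to NMR-inactive 12C --
    the reservoir used by homonuclear modules.  The two heteronuclear pools
    are the satellite protons directly bound to 1.1%-abundant 13C and to
    0.4%-abundant 15N.
    """

    BULK_1H = "BULK_1H"
    C13_BOUND_1H = "C13_BOUND_1H"
    N15_BOUND_1H = "N15_BOUND_1H"


class ModuleCategory(str, Enum):
    HET_13C = "HET_13C"
    HET_15N = "HET_15N"
    HOMONUCLEAR = "HOMONUCLEAR"
    PURESHIFT_2DJ = "PURESHIFT_2DJ"


class ParameterKind(str, Enum):
    PULSE = "PULSE"            # p#
    DELAY = "DELAY"            # d#
    CONSTANT = "CONSTANT"      # cnst#
    GRAD_AMP = "GRAD_AMP"      # gpz#
    GRAD_NAME = "GRAD_NAME"    # gpnam#
    PHASE = "PHASE"            # ph#
    LOCAL_DELAY = "LOCAL_DELAY"  # named identifier, e.g. DC_HSQC1


_KIND_PREFIX = {
    ParameterKind.PULSE: "p",
    ParameterKind.DELAY: "d",
    ParameterKind.CONSTANT: "cnst",
    ParameterKind.GRAD_AMP: "gpz",
    ParameterKind.GRAD_NAME: "gpnam",
    ParameterKind.PHASE: "ph",
}


@dataclass(frozen=True)
class Parameter:
    kind: ParameterKind
    index_or_name: object  # int for numbered kinds, str for LOCAL_DELAY
    definition: str = ""   # relation rendered as "name=expr"; empty = user-set
    ased_comment: str = ""

    @property
    def token(self) -> str:
        """The symbol as it appears in pulse program text (p1, cnst2, DC_HSQC1)."""
        if self.kind is ParameterKind.LOCAL_DELAY:
            return str(self.index_or_name)
        return f"{_KIND_PREFIX[self.kind]}{self.index_or_name}"

    @property
    def key(self):
        return (self.kind, self.index_or_name)


@dataclass(frozen=True)
class PhaseCycle:
    index: int
    steps: tuple[str, ...]   # over {"x", "-x", "y", "-y"}
    is_receiver: bool = False

    _STEP_TO_BRUKER = {"x": "0", "y": "1", "-x": "2", "-y": "3"}

    def __post_init__(self):
        if len(self.steps) not in (1, 2, 4, 8, 16):
            raise ValueError(f"ph{self.index}: cycle length {len(self.steps)} not in 1/2/4/8/16")
        bad = [s for s in self.steps if s not in self._STEP_TO_BRUKER]
        if bad:
            raise ValueError(f"ph{self.index}: bad phase steps {bad}")

    @property
    def token(self) -> str:
        return f"ph{self.index}"

    def render(self) -> str:
        """Bruker phase definition line, e.g. ``ph1=0 2``."""
        return f"ph{self.index}=" + " ".join(self._STEP_TO_BRUKER[s] for s in self.steps)


@dataclass(frozen=True)
class GradientSpec:
    index: int
    amplitude: float        # percent of max gradient strength; magnitude if echo_antiecho
    duration: float         # milliseconds
    shape: str = "SMSQ10.100"
    echo_antiecho: bool = False  # sign alternates between FIDs (CTP selection)

    def __post_init__(self):
        if abs(self.amplitude) > 100:
            raise ValueError(f"gpz{self.index}: |amplitude| > 100%")
        if self.duration <= 0:
            raise ValueError(f"gpz{self.index}: duration must be positive")

    @property
    def token(self) -> str:
        return f"gpz{self.index}"


@dataclass(frozen=True)
class CouplingConstants:
    """Scalar couplings (Hz) from which transfer delays are derived."""

    one_bond_JCH: float = 145.0
    long_range_JCH: float = 5.0
    one_bond_JNH: float = 90.0

    def __post_init__(self):
        for name in ("one_bond_JCH", "long_range_JCH", "one_bond_JNH"):
            if getattr(self, name) <= 0:
                raise NonPositiveCoupling(f"{name} must be > 0 Hz")


DEFAULT_COUPLINGS = CouplingConstants()


@dataclass(frozen=True)
class ShapedPulse:
    name: str        # sp#
    pulse: str       # associated pulse width token, e.g. p24
    directive: str   # WaveMaker body, emitted as ;sp#:wvm:<directive>


@dataclass(frozen=True)
class VariantDefinition:
    label: str
    retains: frozenset[MagnetizationPool]
    block: str  # text substituted for the {{ZZ_FILTER}} placeholder


@dataclass(frozen=True)
class IndirectDimension:
    t1_delay: str               # local delay incremented between increments
    echo_antiecho: bool = False
    ea_gradient: Optional[int] = None  # gpz index whose sign alternates


@dataclass(frozen=True)
class ModuleDefinition:
    abbreviation: str
    display_name: str
    category: ModuleCategory
    slot: str  # hmbc / n15 / c13 / h1 -- the selection slot the module occupies
    pools_required: frozenset[MagnetizationPool]
    pools_consumed: frozenset[MagnetizationPool]
    pools_preserved: frozenset[MagnetizationPool]
    parameters: tuple[Parameter, ...]
    phase_cycles: tuple[PhaseCycle, ...]
    gradients: tuple[GradientSpec, ...]
    body_template: str
    au_program: str
    variants: tuple[VariantDefinition, ...] = ()
    supports_flags: frozenset[str] = frozenset()
    shaped_pulses: tuple[ShapedPulse, ...] = ()
    indirect: Optional[IndirectDimension] = None
    zip_block: str = ""  # seHSQC only: bulk-preserving ZIP element
    k_scaling: bool = False   # t1 increments may be traded for transients
    sapphire: bool = False    # SAPPHIRE zero-point averaging available
    variant_label: Optional[str] = None  # set when a variant has been applied

    @property
    def pools_partial(self) -> frozenset[MagnetizationPool]:
        """Pools that survive only partially (tolerated-loss reuse)."""
        return self.pools_consumed & self.pools_preserved

    def variant_labels(self) -> tuple[str, ...]:
        return tuple(v.label for v in self.variants)

    def with_variant(self, label: str) -> "ModuleDefinition":
        """Return this definition with the named variant's block substituted.

        The variant's ``retains`` set replaces the heteronuclear part of
        ``pools_preserved``; bulk-pool semantics are unchanged.
        """
        for v in self.variants:
            if v.label == label:
                het = {MagnetizationPool.C13_BOUND_1H, MagnetizationPool.N15_BOUND_1H}
                preserved = (self.pools_preserved - het) | v.retains
                block = "\n".join("  " + ln if ln.strip() else ln
                                  for ln in v.block.rstrip("\n").splitlines())
                body = self.body_template.replace("{{ZZ_FILTER}}", block)
                return replace(
                    self,
                    pools_preserved=frozenset(preserved),
                    body_template=body,
                    variants=(),
                    variant_label=label,
                )
        raise UnknownVariant(
            f"module {self.abbreviation!r} has no variant {label!r}; "
            f"known: {', '.join(self.variant_labels()) or '(none)'}"
        )

    def defined_tokens(self) -> set[str]:
        """All symbols this module's tables define (for completeness checks)."""
        toks = {p.token for p in self.parameters}
        toks |= {c.token for c in self.phase_cycles}
        toks |= {f"gpz{g.index}" for g in self.gradients}
        toks |= {f"gp{g.index}" for g in self.gradients}
        toks |= {s.name for s in self.shaped_pulses}
        return toks


TOKEN_RE = re.compile(
    r"\b(p\d+|d\d+|cnst\d+|gpz\d+|gp\d+|ph\d+|sp\d+|D[CNH]_[A-Z0-9]+)\b"
)


def body_tokens(text: str) -> set[str]:
    """Symbols referenced by pulse program body text (comments stripped)."""
    toks: set[str] = set()
    for line in text.splitlines():
        code = line.split(";", 1)[0]
        if code.strip().startswith("#"):  # #ifdef SYMBOL etc.
            continue
        toks.update(TOKEN_RE.findall(code))
    return toks


# ---------------------------------------------------------------------------
# registry loading
# ---------------------------------------------------------------------------

def _param_from_dict(d: Mapping) -> Parameter:
    kind = ParameterKind(d["kind"])
    idx = d["id"]
    if kind is not ParameterKind.LOCAL_DELAY:
        idx = int(idx)
    return Parameter(kind, idx, d.get("definition", "") or "", d.get("comment", "") or "")


class Registry:
    """All shipped module definitions, keyed by abbreviation."""

    def __init__(self, modules: Iterable[ModuleDefinition]):
        self._modules: dict[str, ModuleDefinition] = {}
        for m in modules:
            if m.abbreviation in self._modules:
                raise ValueError(f"duplicate module abbreviation {m.abbreviation!r}")
            self._modules[m.abbreviation] = m

    @classmethod
    def load(cls) -> "Registry":
        pkg = resources.files("noahgen") / "registry"
        common = yaml.safe_load((pkg / "_common.yaml").read_text(encoding="utf-8"))
        mods = []
        for entry in sorted(p.name for p in pkg.iterdir() if p.name.endswith(".yaml")):
            if entry.startswith("_"):
                continue
            doc = yaml.safe_load((pkg / entry).read_text(encoding="utf-8"))
            mods.append(_module_from_doc(doc, common))
        return cls(mods)

    def abbreviations(self) -> tuple[str, ...]:
        return tuple(sorted(self._modules))

    def __contains__(self, abbr: str) -> bool:
        return abbr in self._modules

    def __len__(self) -> int:
        return len(self._modules)

    def get(self, abbreviation: str, variant_label: Optional[str] = None) -> ModuleDefinition:
        try:
            mod = self._modules[abbreviation]
        except KeyError:
            raise UnknownModule(
                f"unknown module {abbreviation!r}; known: {', '.join(self.abbreviations())}"
            ) from None
        if variant_label is not None:
            return mod.with_variant(variant_label)
        return mod

    def restricted(self, abbreviations: Iterable[str]) -> "Registry":
        """A view containing only the given modules (used for enumeration tests)."""
        keep = set(abbreviations)
        missing = keep - set(self._modules)
        if missing:
            raise UnknownModule(f"unknown modules {sorted(missing)}")
        return Registry(m for a, m in self._modules.items() if a in keep)


def _module_from_doc(doc: Mapping, common: Mapping) -> ModuleDefinition:
    # expand shared entries referenced via the `use` list
    params = [_param_from_dict(common["parameters"][k]) for k in doc.get("use", [])
              if k in common["parameters"]]
    params += [_param_from_dict(d) for d in doc.get("parameters", [])]
    phases = [PhaseCycle(c["index"], tuple(str(s) for s in c["steps"]),
                         bool(c.get("receiver", False)))
              for c in common.get("phase_cycles", [])
              if f"ph{c['index']}" in doc.get("use", [])]
    phases += [PhaseCycle(c["index"], tuple(str(s) for s in c["steps"]),
                          bool(c.get("receiver", False)))
               for c in doc.get("phase_cycles", [])]
    grads = [GradientSpec(g["index"], float(g["amplitude"]), float(g["duration"]),
                          str(g.get("shape", "SMSQ10.100")), bool(g.get("echo_antiecho", False)))
             for g in common.get("gradients", [])
             if f"gpz{g['index']}" in doc.get("use", [])]
    grads += [GradientSpec(g["index"], float(g["amplitude"]), float(g["duration"]),
                           str(g.get("shape", "SMSQ10.100")), bool(g.get("echo_antiecho", False)))
              for g in doc.get("gradients", [])]
    shaped = [ShapedPulse(s["name"], s.get("pulse", ""), s["directive"])
              for s in common.get("shaped_pulses", [])
              if s["name"] in doc.get("use", [])]
    shaped += [ShapedPulse(s["name"], s.get("pulse", ""), s["directive"])
               for s in doc.get("shaped_pulses", [])]

    body = doc["body"]
    for name, block in common.get("blocks", {}).items():
        body = body.replace("{{%s}}" % name, block.rstrip("\n"))

    pools = doc["pools"]
    variants = tuple(
        VariantDefinition(v["label"],
                          frozenset(MagnetizationPool(p) for p in v.get("retains", [])),
                          v["block"])
        for v in doc.get("variants", [])
    )
    ind = None
    if doc.get("indirect"):
        d = doc["indirect"]
        ind = IndirectDimension(d["t1_delay"], bool(d.get("echo_antiecho", False)),
                                d.get("ea_gradient"))
    return ModuleDefinition(
        abbreviation=doc["abbreviation"],
        display_name=doc["display_name"],
        category=ModuleCategory(doc["category"]),
        slot=doc["slot"],
        pools_required=frozenset(MagnetizationPool(p) for p in pools.get("required", [])),
        pools_consumed=frozenset(MagnetizationPool(p) for p in pools.get("consumed", [])),
        pools_preserved=frozenset(MagnetizationPool(p) for p in pools.get("preserved", [])),
        parameters=tuple(params),
        phase_cycles=tuple(phases),
        gradients=tuple(grads),
        body_template=body,
        au_program=doc["au_program"],
        variants=variants,
        supports_flags=frozenset(doc.get("supports_flags", [])),
        shaped_pulses=tuple(shaped),
        indirect=ind,
        zip_block=doc.get("zip_block", ""),
        k_scaling=bool(doc.get("k_scaling", False)),
        sapphire=bool(doc.get("sapphire", False)),
    )


_default_registry: Optional[Registry] = None


def default_registry() -> Registry:
    global _default_registry
    if _default_registry is None:
        _default_registry = Registry.load()
    return _default_registry


def get_module(abbreviation: str, variant_label: Optional[str] = None) -> ModuleDefinition:
    """Look up a module definition (optionally with a variant applied)."""
    return default_registry().get(abbreviation, variant_label)


# ---------------------------------------------------------------------------
# computed physics
# ---------------------------------------------------------------------------

def compute_delays(constants: CouplingConstants = DEFAULT_COUPLINGS) -> dict[str, float]:
    """Transfer delays (seconds) from scalar couplings.

    DELTA    = 1/(4 * 1J_CH)   one-bond 1H-13C INEPT delay
    DELTA_LR = 1/(2 * nJ_CH)   long-range HMBC evolution delay
    DELTA_N  = 1/(4 * 1J_NH)   one-bond 1H-15N transfer delay
    """
    return {
        "DELTA": 1.0 / (4.0 * constants.one_bond_JCH),
        "DELTA_LR": 1.0 / (2.0 * constants.long_range_JCH),
        "DELTA_N": 1.0 / (4.0 * constants.one_bond_JNH),
    }


def ctp_gradient_amplitude(g1_amplitude: float, gamma_ratio: float,
                           n_gradients: int) -> float:
    """Refocusing-gradient amplitude for CTP selection, in percent.

    Each of the ``n_gradients`` PFGs bracketing t1 dephases X-nucleus
    single-quantum coherence by ``g1 * |gamma_X / gamma_H|`` in proton
    units; the final proton-frequency refocusing gradient must match their
    sum.  Amplitudes are rounded to one decimal place per gradient (the
    spectrometer setting granularity) before summation.
    """
    if n_gradients < 1:
        raise ValueError("n_gradients must be >= 1")
    if not 0 < g1_amplitude <= 100:
        raise ValueError("g1_amplitude must lie in (0, 100]")
    per_gradient = round(g1_amplitude * abs(gamma_ratio), 1)
    return round(n_gradients * per_gradient, 1)
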