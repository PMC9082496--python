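"""Acquisition flags (zgoptns symbols) and NUS schedule generation.

Optional features — multiplicity editing, solvent suppression, zero-quantum
suppression, nonuniform sampling — are compiled conditionally via symbols
in the ``zgoptns`` TopSpin parameter (``-DPRESAT`` etc.).  The guarded
blocks are *always* present in the generated text, so one pulse program
serves both the flag-on and flag-off experiment; applying flags only
records the requested symbols in the header.

NUS support needs a sampled list of t1 increments as a sidecar file; the
generator here samples uniformly at random without replacement, always
keeping the first increment (which anchors the interferogram).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Callable, Iterable

from .errors import BadFraction, UnknownFlag
from .module_library import ModuleCategory
from .assembler import PulseProgramText


@dataclass(frozen=True)
class AcquisitionFlag:
    symbol: str
    effect: str
    applicable_modules: Callable[[ModuleCategory], bool]


_HOMO = (ModuleCategory.HOMONUCLEAR,)
_HET = (ModuleCategory.HET_13C, ModuleCategory.HET_15N)

FLAGS: dict[str, AcquisitionFlag] = {
    "PRESAT": AcquisitionFlag(
        "PRESAT",
        "presaturation during the recovery delay and NOESY mixing times",
        lambda c: True),  # acts on the shared recovery delay
    "ES": AcquisitionFlag(
        "ES",
        "excitation sculpting (shaped + hard 180) before homonuclear acquisition",
        lambda c: c in _HOMO),
    "EDIT": AcquisitionFlag(
        "EDIT",
        "multiplicity editing in HSQC-type modules",
        lambda c: c in _HET),
    "ZQS": AcquisitionFlag(
        "ZQS",
        "zero-quantum suppression (swept pulse + weak PFG)",
        lambda c: c in _HOMO),
    "NUS": AcquisitionFlag(
        "NUS",
        "nonuniform sampling of the indirect dimension(s)",
        lambda c: True),
}


def apply_flags(text: PulseProgramText, flags: Iterable[str]) -> PulseProgramText:
    """Record acquisition flags in the program header.

    The conditional blocks themselves are always emitted by the assembler;
    this only rewrites the ``;zgoptns:`` header line (and validates the
    symbols), mirroring how a spectrometer user would toggle features.
    """
    requested = sorted(set(flags))
    unknown = [f for f in requested if f not in FLAGS]
    if unknown:
        raise UnknownFlag(f"unknown acquisition flag(s) {unknown}; "
                          f"known: {sorted(FLAGS)}")
    zg = ";zgoptns: " + (" ".join(f"-D{f}" for f in requested)
                         if requested else "(none requested)")
    header = tuple(zg if ln.startswith(";zgoptns:") else ln
                   for ln in text.header)
    return replace(text, header=header)


@dataclass(frozen=True)
class NusSchedule:
    td1_full: int
    sampled_increments: tuple[int, ...]  # sorted, unique, starts at 1
    fraction: float
    seed: int

    def render(self) -> str:
        """Sidecar list file: one increment per line."""
        return "\n".join(str(i) for i in self.sampled_increments) + "\n"


def generate_nus_schedule(td1_full: int, fraction: float, seed: int) -> NusSchedule:
    """Sample ``round(fraction * td1_full)`` increments from 1..td1_full.

    Deterministic for a given seed; increment 1 is always included;
    ``fraction=1`` returns the full uniform grid.
    """
    if td1_full < 2:
        raise ValueError("td1_full must be >= 2")
    if not 0 < fraction <= 1:
        raise BadFraction(f"fraction {fraction} outside (0, 1]")
    n = max(1, round(fraction * td1_full))
    rng = random.Random(seed)
    rest = rng.sample(range(2, td1_full + 1), n - 1)
    incs = tuple(sorted({1, *rest}))
    return NusSchedule(td1_full=td1_full, sampled_increments=incs,
                       fraction=fraction, seed=seed)
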