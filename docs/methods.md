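# Methods

## The magnetization-pool model

Proton magnetization at thermal equilibrium is partitioned into three
pools: `BULK_1H` (protons on NMR-inactive ¹²C — the reservoir homonuclear
experiments observe), `C13_BOUND_1H` (the 1.1 %-abundance ¹³C satellites)
and `N15_BOUND_1H` (the ¹⁵N satellites). Every registry module declares
three sets over these pools:

* `required` — what the experiment observes;
* `consumed` — what it tips away from +*z*;
* `preserved` — what it returns to +*z*.

A pool in both `consumed` and `preserved` survives **partially**: later
use is possible but costs sensitivity. This single declaration encodes all
the "tolerated loss" cases:

* the zz-HMBC consumes bulk but partially preserves it (ASAP mixing
  between modules replenishes the pool, and any bulk-observing module is
  far more sensitive than the HMBC anyway);
* COSY/TOCSY-type modules partially preserve bulk, so one further
  bulk-observing module (e.g. COSY → NOESY) may follow;
* the HSQC-TOCSY partially preserves the ¹³C pool — its relay spreads
  ¹³C-bound magnetization through the spin system — so exactly one further
  ¹³C module may follow it;
* NOESY/ROESY and the pure shift / 2DJ modules preserve nothing (long
  mixing or pseudo-2D chunk acquisition scrambles what remains), which is
  also why a pure shift module is always terminal without any explicit
  "last position" rule.

The pool trace assigns each pool a state `INTACT → PARTIAL → CONSUMED`
after every module. A module whose required pool is `CONSUMED` is a fatal
diagnostic; `PARTIAL` is a non-fatal tolerated-loss note.

## Viability rules

Four structural rules supplement the trace, because they express
sensitivity/ordering conventions the pool algebra cannot:

1. length 2–5 and no repeated module;
2. an HMBC module must lead the supersequence (its zz-filter is designed
   for equilibrium magnetization; placing anything before it degrades both
   the HMBC and the filter's retention);
3. ¹⁵N modules precede ¹³C modules (the less sensitive experiment runs on
   the fresher magnetization — the universal practice in published
   supersequences);
4. at most two ¹³C modules and at most two bulk-observing
   (homonuclear + pure shift) modules.

Developer mode does not change the verdict; the build pipeline demotes
fatal diagnostics to warnings and proceeds.

`enumerate_viable` is a depth-first search pruned by the prefix property
(every rule is monotone under extension, so a non-viable prefix cannot be
completed); the test suite keeps an independent brute-force oracle that
filters all ordered selections. Under the shipped 15-module inventory
(B; M, SNp; S, Sp, St; C, Cc, T, N, R; P, Pt, J, Jqf) these rules yield
**1112** viable supersequences, a number the suite recomputes both ways.
The count scales with the registry: it is a property of this inventory and
rule reconstruction, not a universal constant, and adding modules (more
¹⁵N experiments, HSQC-COSY variants, parallel acquisition schemes…) grows
it quickly.

## Variant resolution and glue

The zz-HMBC ships four filter variants (`C_HMBC_A/C/N/CN`). The choice is
a pure function of the *later* modules' required pools: retain exactly the
heteronucleus-bound pools someone downstream needs. In developer mode an
explicit `--variant B=LABEL` override wins verbatim.

The seHSQC ZIP element (a bulk-restoring sandwich prepended to the module)
is included iff a later module consumes `BULK_1H`; when the seHSQC is
last, it is omitted — the element costs sensitivity and protects nothing.

Between modules: ASAP isotropic mixing is inserted immediately before the
first homonuclear module when an HMBC precedes it; every other boundary
receives a purge pulse + PFG. Two deliberately conservative choices, both
open design points: ASAP is suppressed when that homonuclear module is a
NOESY (isotropic mixing immediately before NOE buildup would perturb the
initial condition; the `FORCEASAP` option restores it), and TOCSY /
CLIP-COSY are treated exactly like COSY.

## Parameters, phases, gradients

Parameters are standardized registry-wide so concatenation can never
clash: shared slots (hard pulses `p1–p4`, `p21/p22`, coupling constants
`cnst2/cnst4/cnst13`, gradient recovery `d16`…) are defined once in
`_common.yaml` and referenced by modules, which also makes duplicate
collation trivially mergeable; module-specific delays use readable local
identifiers `D<nucleus>_<MODULE><n>` (e.g. `DC_HSQC1 = 1/(4·¹J꜀ₕ)`)
declared via `define delay`. Phase-cycle indices are allocated disjointly
(ph1–ph16 pulse phases, ph17–ph31 receivers, ph0 the shared constant-x),
and gradient indices gpz0–gpz31 likewise, so any module combination
collates without renumbering; a genuine collision is a curation error and
raises, never silently renumbers. Each module carries exactly one receiver
cycle; the program-wide receiver list is the ordered per-module sequence
(one FID per module is the whole point of the acquisition scheme).

Default coupling constants are ¹J꜀ₕ = 145 Hz, ⁿJ꜀ₕ = 5 Hz,
¹J_NH = 90 Hz — conventional small-molecule values, overridable via a YAML
config. Gyromagnetic ratios are fixed at γ_H = 26.7522128×10⁷,
γ_C = 6.728284×10⁷, γ_N = −2.7126×10⁷ rad s⁻¹ T⁻¹. CTP gradient ratios
round to one decimal place *per gradient* before summation, matching
spectrometer amplitude granularity: 80 % × |γ_N/γ_H| → 8.1 %, so the
two-PFG ¹⁵N scheme refocuses at ±16.2 % and the ¹³C decode gradient is
20.1 %.

## The generated dialect

The output is a deliberately small Bruker-style subset: `;` comments,
`define delay NAME`, `"NAME=expr"` relations, `#ifdef SYMBOL … #else …
#endif` conditionals, `goscnp ph#` per-module acquisition, and an explicit
loop/increment tail in place of TopSpin's `mc` macro (`igrad EA#` marks
echo–antiecho sign inversion of the designated gradient between FIDs).
Nine sections appear in fixed order, delimited by marker comments, and the
footer is one datum per line (`;MODULES:`, `;AUPROG:`, `;VERSION:`,
`;TIMESTAMP:`) so the processing chain can parse it with no state.
Timestamps are injectable ISO-8601 UTC strings, making assembly
byte-deterministic for fixed metadata. Conformance is defined by the
shipped linter (symbol table per section, duplicate detection, guard
balance and known-flag guards, section order, footer grammar); TopSpin
byte-level fidelity is explicitly not claimed.

Acquisition-flag blocks are *always* emitted, guarded; applying flags only
rewrites the `;zgoptns:` header line. One program therefore serves every
flag combination, and the linter is run (in the suite) over flag subsets
to guarantee no guard orphans a definition.

## NUS schedules

`generate_nus_schedule(td1, fraction, seed)` samples
`round(fraction·td1)` increments uniformly at random without replacement,
always including increment 1 (the interferogram anchor), sorted, written
one per line to a sidecar file. Uniform sampling is the simplest
defensible default — the weighting is pluggable and nothing downstream
assumes it. Determinism is by explicit seed; a histogram test over 1000
seeds checks that no increment is systematically excluded.

## What the tests do and do not show

Everything here is desk-scale: the suite verifies the generated *text* —
registry completeness, pool combinatorics against a brute-force oracle,
the decision tables, lint-cleanliness and footer round-trip over all 1112
enumerated sequences, determinism, schedule invariants — and the tabulated
pulse-program constants. It cannot verify spectrometer behaviour: no spin
dynamics are simulated, so artifact suppression, sensitivity and solvent
suppression performance of the generated sequences are out of scope, as
are processing-script internals and vendor dialects other than Bruker's.
Module bodies are abridged (structurally faithful skeletons carrying the
full parameter/phase/gradient tables), not full production sequences.
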