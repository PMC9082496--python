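# noahgen

Offline generator, combinatorics engine and linter for **NOAH supersequence
pulse programs** (Bruker dialect).

NOAH experiments (*NMR by Ordered Acquisition using ¹H detection*)
concatenate up to five 2D NMR modules — HMBC, HSQC, HMQC, COSY, NOESY,
pure shift experiments, … — into a single *supersequence* that shares one
recovery delay, cutting total experiment time by up to 4×. The trick is
magnetization bookkeeping: each module must excite only the proton pool it
needs (bulk ¹²C-bound protons, ¹³C satellites, or ¹⁵N satellites) and leave
the rest along +*z* for the modules that follow. Writing the resulting
many-hundred-line pulse programs by hand is slow and error-prone, and the
number of useful module combinations runs into the thousands.

`noahgen` assembles these programs automatically from a data-driven module
registry. For structure-elucidation spectroscopists and probe/pulse-sequence
developers it provides:

* **a module registry** (15 modules as structured YAML: parameters, phase
  cycles, gradient tables, pulse program bodies, zz-filter variants);
* **viability checking** — a per-pool magnetization trace
  (`INTACT → PARTIAL → CONSUMED`) plus ordering rules, so `S,C` (HSQC then
  COSY) is accepted while `C,S` is rejected: a leading COSY consumes the
  ¹³C-bound magnetization the HSQC needs;
* **enumeration** of every viable 2–5-module supersequence;
* **context-sensitive resolution**: the HMBC zz-filter variant is chosen
  from what later modules need, the seHSQC ZIP element is inserted only
  when bulk magnetization must survive, and ASAP mixing / purge gradients
  are placed between modules;
* **assembly** into a nine-section, byte-deterministic pulse program with
  collated parameters, merged phase cycles, `gppp`/WaveMaker/`ased`
  annotations and a machine-parseable provenance footer;
* **acquisition flags** (`-DEDIT`, `-DES`, `-DPRESAT`, `-DZQS`, `-DNUS`)
  as conditional-compilation guards, plus **NUS schedule generation**;
* **a linter** that enforces the dialect (symbol table, duplicates, guard
  balance, section order, footer grammar).

Key physics carried by the registry and checked by the test suite: INEPT
and HMBC delays Δ = 1/(4·¹J꜀ₕ), Δ_LR = 1/(2·ⁿJ꜀ₕ); coherence-transfer-
pathway gradient ratios g₂ = n·g₁·|γₓ/γₕ| (80 % → 20.1 % for ¹³C,
80 % → n·8.1 % for ¹⁵N); the zz-HMBC gradient/phase tables
(−15, 10, 5, 80, ±40.2 %, all 1 ms; φ₁ = x,−x; φ₂ = x,x,−x,−x;
φ_rec = x,−x,−x,x) including the ¹³C 90° purge pulse that suppresses
one-bond artifacts; and the two-PFG (2.5 ms) ¹⁵N HMQC t₁ bracketing that
suppresses wing artifacts in downstream modules.

## Worked example

Ask why HSQC-before-COSY works but not the reverse:

```text
$ noahgen explain C,S
C,S: NOT viable
  fatal at position 2 [C13_BOUND_1H]: module S needs C13_BOUND_1H, which an earlier module has consumed
```

Build a NOAH-3 BSC (HMBC + HSQC + COSY) program:

```text
$ noahgen build --modules B,S,C --timestamp 2022-01-20T00:00:00Z --out bsc.txt
warning: module C draws on partially depleted BULK_1H (tolerated loss)
wrote bsc.txt
```

The warning is the *tolerated loss*: HMBC and COSY share the bulk pool, but
the COSY is so much more sensitive than the HMBC that the loss is accepted
(and an ASAP mixing block is inserted before the COSY to replenish the
pool). The file starts and ends like this:

```text
; noah3-BSC
; NOAH-3 supersequence: 13C HMBC (zz-filter) + 13C HSQC + COSY
...
;MODULES: B,S,C
;AUPROG: noah_hmbc,noah_hsqc,noah_cosy
;VERSION: 2.1.0
;TIMESTAMP: 2022-01-20T00:00:00Z
```

The footer is the contract consumed by the split-and-process chain: the
processing script recovers the per-module AU programs (`noah_hmbc`,
`noah_hsqc`, `noah_cosy`) by parsing the pulse program text, so no manual
processing parameters are needed. Because the sequence contains an HMBC
followed by a ¹³C module, the zz-filter variant `C_HMBC_C` (retain
¹³C-bound magnetization) was selected automatically — visible in the main
block as `;=== module 1 of 3: B (13C HMBC (zz-filter), variant C_HMBC_C) ===`.

Count the combinatorial space, and validate any program:

```text
$ noahgen enumerate
1112 viable supersequences (lengths 2-5)
$ noahgen lint bsc.txt
bsc.txt: OK (2 warning(s))
```

Other subcommands: `list-modules`, `nus --td1 128 --fraction 0.5 --seed 42
--out nus.list`, `parse-footer FILE`, and `build --developer` to bypass
viability checking (any module combination, warnings instead of errors,
`--variant B=C_HMBC_N` overrides allowed).

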