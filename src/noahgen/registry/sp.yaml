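# 13C sensitivity-enhanced HSQC ("S+").  When a later module needs bulk 1H,
# the ZIP element is prepended (assembly-time {{ZIP}} substitution) to return
# bulk magnetization to +z; when the module is last, ZIP is omitted to
# maximize sensitivity.
abbreviation: Sp
display_name: 13C seHSQC (S+)
category: HET_13C
slot: c13
au_program: noah_hsqc
pools:
  required: [C13_BOUND_1H]
  consumed: [C13_BOUND_1H]
  preserved: [BULK_1H, N15_BOUND_1H]
supports_flags: [EDIT, NUS, PRESAT]
use: [p1, p2, p3, p4, p16, d16, cnst2, ph0]
parameters:
  - {kind: LOCAL_DELAY, id: DC_SEHSQC1, definition: "0.25s/cnst2",
     comment: "INEPT transfer delay, 1/(4 * 1J(CH))"}
  - {kind: LOCAL_DELAY, id: DC_SEHSQC2, definition: "0.125s/cnst2",
     comment: "PEP back-transfer delay, 1/(8 * 1J(CH)) (CH/CH2 compromise)"}
  - {kind: LOCAL_DELAY, id: DC_SEHSQC3, definition: "3u",
     comment: "t1/2 evolution delay (incremented)"}
  - {kind: LOCAL_DELAY, id: DC_SEHSQC4, definition: "0.5s/cnst2",
     comment: "multiplicity editing delay, 1/(2 * 1J(CH))"}
phase_cycles:
  - {index: 4, steps: [x, -x]}
  - {index: 19, steps: [x, -x], receiver: true}
gradients:
  - {index: 8, amplitude: 80.0, duration: 1.0, shape: SMSQ10.100, echo_antiecho: true}
  - {index: 9, amplitude: 20.1, duration: 1.0, shape: SMSQ10.100}
  - {index: 26, amplitude: 13.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DC_SEHSQC3
  echo_antiecho: true
  ea_gradient: 8
zip_block: |2
    ; ZIP element: return bulk 1H to +z before the seHSQC proper
    (p1 ph0):f1
    DC_SEHSQC1
    (p2 ph0):f1 (p4 ph0):f2
    DC_SEHSQC1
    (p1 ph0):f1
    p16:gp26
    d16
body: |2
  {{ZIP}}
    ; INEPT
    (p1 ph0):f1
    DC_SEHSQC1
    (p2 ph0):f1 (p4 ph0):f2
    DC_SEHSQC1
    (p1 ph0):f1 (p3 ph4):f2
    ; t1 evolution with echo-antiecho encoding
    DC_SEHSQC3
    (p2 ph0):f1
    DC_SEHSQC3
    p16:gp8
    d16
  #ifdef EDIT
    ; multiplicity editing spin echo
    DC_SEHSQC4
    (p2 ph0):f1 (p4 ph0):f2
    DC_SEHSQC4
  #endif
    ; sensitivity-enhanced (PEP) back transfer
    (p1 ph0):f1 (p3 ph0):f2
    DC_SEHSQC1
    (p2 ph0):f1 (p4 ph0):f2
    DC_SEHSQC2
    (p1 ph0):f1 (p3 ph0):f2
    DC_SEHSQC2
    (p2 ph0):f1
    p16:gp9
    d16
    goscnp ph19
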