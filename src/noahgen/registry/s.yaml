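# 13C HSQC module: excites only 13C-bound 1H (satellites), returning bulk
# magnetization to +z for downstream modules.  Echo-antiecho selection via
# sign alternation of the 80% encoding gradient; decode amplitude is
# 80 * |gamma(13C)/gamma(1H)| = 20.1%.
abbreviation: S
display_name: 13C HSQC
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
  - {kind: LOCAL_DELAY, id: DC_HSQC1, definition: "0.25s/cnst2",
     comment: "INEPT transfer delay, 1/(4 * 1J(CH))"}
  - {kind: LOCAL_DELAY, id: DC_HSQC2, definition: "0.5s/cnst2",
     comment: "multiplicity editing delay, 1/(2 * 1J(CH))"}
  - {kind: LOCAL_DELAY, id: DC_HSQC3, definition: "3u",
     comment: "t1/2 evolution delay (incremented)"}
phase_cycles:
  - {index: 3, steps: [x, -x]}
  - {index: 18, steps: [x, -x], receiver: true}
gradients:
  - {index: 6, amplitude: 80.0, duration: 1.0, shape: SMSQ10.100, echo_antiecho: true}
  - {index: 7, amplitude: 20.1, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DC_HSQC3
  echo_antiecho: true
  ea_gradient: 6
body: |2
    ; INEPT: 1H -> 13C for satellite protons only
    (p1 ph0):f1
    DC_HSQC1
    (p2 ph0):f1 (p4 ph0):f2
    DC_HSQC1
    (p1 ph0):f1 (p3 ph3):f2
    ; t1 evolution with echo-antiecho encoding
    DC_HSQC3
    (p2 ph0):f1
    DC_HSQC3
    p16:gp6
    d16
  #ifdef EDIT
    ; multiplicity editing spin echo
    DC_HSQC2
    (p2 ph0):f1 (p4 ph0):f2
    DC_HSQC2
  #endif
    ; back-INEPT, bulk 1H returned to +z
    (p1 ph0):f1 (p3 ph0):f2
    DC_HSQC1
    (p2 ph0):f1 (p4 ph0):f2
    DC_HSQC1
    p16:gp7
    d16
    goscnp ph18
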