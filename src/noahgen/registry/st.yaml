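# 13C HSQC-TOCSY ("ST").  The terminal DIPSI-2 relay redistributes
# 13C-bound proton magnetization through the spin system, so a further
# 13C module may follow with tolerated partial loss (C13 pool marked as
# partially surviving).
abbreviation: St
display_name: 13C HSQC-TOCSY (ST)
category: HET_13C
slot: c13
au_program: noah_hsqctocsy
pools:
  required: [C13_BOUND_1H]
  consumed: [C13_BOUND_1H]
  preserved: [BULK_1H, N15_BOUND_1H, C13_BOUND_1H]
supports_flags: [EDIT, NUS, PRESAT]
use: [p1, p2, p3, p4, p6, p16, d9, d16, cnst2, ph0]
parameters:
  - {kind: LOCAL_DELAY, id: DC_HSQCT1, definition: "0.25s/cnst2",
     comment: "INEPT transfer delay, 1/(4 * 1J(CH))"}
  - {kind: LOCAL_DELAY, id: DC_HSQCT2, definition: "3u",
     comment: "t1/2 evolution delay (incremented)"}
  - {kind: LOCAL_DELAY, id: DC_HSQCT3, definition: "0.5s/cnst2",
     comment: "multiplicity editing delay, 1/(2 * 1J(CH))"}
phase_cycles:
  - {index: 5, steps: [x, -x]}
  - {index: 20, steps: [x, -x], receiver: true}
gradients:
  - {index: 10, amplitude: 80.0, duration: 1.0, shape: SMSQ10.100, echo_antiecho: true}
  - {index: 11, amplitude: 20.1, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DC_HSQCT2
  echo_antiecho: true
  ea_gradient: 10
body: |2
    ; INEPT
    (p1 ph0):f1
    DC_HSQCT1
    (p2 ph0):f1 (p4 ph0):f2
    DC_HSQCT1
    (p1 ph0):f1 (p3 ph5):f2
    ; t1 evolution with echo-antiecho encoding
    DC_HSQCT2
    (p2 ph0):f1
    DC_HSQCT2
    p16:gp10
    d16
  #ifdef EDIT
    ; multiplicity editing spin echo
    DC_HSQCT3
    (p2 ph0):f1 (p4 ph0):f2
    DC_HSQCT3
  #endif
    ; back-INEPT
    (p1 ph0):f1 (p3 ph0):f2
    DC_HSQCT1
    (p2 ph0):f1 (p4 ph0):f2
    DC_HSQCT1
    ; DIPSI-2 relay of total duration d9 (redistributes 13C-bound 1H)
    (p6 ph0):f1
    d9
    p16:gp11
    d16
    goscnp ph20
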