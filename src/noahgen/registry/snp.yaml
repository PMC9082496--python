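# 15N sensitivity-enhanced HSQC ("SN+"), using the same two-PFG t1
# bracketing strategy as the 15N HMQC.  ZIP element prepended when a later
# module needs bulk 1H.
abbreviation: SNp
display_name: 15N seHSQC (SN+)
category: HET_15N
slot: n15
au_program: noah_hsqc
pools:
  required: [N15_BOUND_1H]
  consumed: [N15_BOUND_1H]
  preserved: [BULK_1H, C13_BOUND_1H]
supports_flags: [NUS, PRESAT]
k_scaling: true
use: [p1, p2, p16, p19, p21, p22, d16, cnst4, cnst37, ph0]
parameters:
  - {kind: LOCAL_DELAY, id: DN_SEHSQC1, definition: "0.25s/cnst4",
     comment: "INEPT transfer delay, 1/(4 * 1J(NH))"}
  - {kind: LOCAL_DELAY, id: DN_SEHSQC2, definition: "0.125s/cnst4",
     comment: "PEP back-transfer delay, 1/(8 * 1J(NH))"}
  - {kind: LOCAL_DELAY, id: DN_SEHSQC3, definition: "3u",
     comment: "t1/2 evolution delay (incremented)"}
phase_cycles:
  - {index: 7, steps: [x, -x]}
  - {index: 22, steps: [x, -x], receiver: true}
gradients:
  - {index: 14, amplitude: 80.0, duration: 2.5, shape: SMSQ10.100}
  - {index: 15, amplitude: 16.2, duration: 2.5, shape: SMSQ10.100, echo_antiecho: true}
  - {index: 27, amplitude: 13.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DN_SEHSQC3
  echo_antiecho: true
  ea_gradient: 15
zip_block: |2
    ; ZIP element: return bulk 1H to +z before the seHSQC proper
    (p1 ph0):f1
    DN_SEHSQC1
    (p2 ph0):f1 (p22 ph0):f3
    DN_SEHSQC1
    (p1 ph0):f1
    p16:gp27
    d16
body: |2
  {{ZIP}}
    ; INEPT
    (p1 ph0):f1
    DN_SEHSQC1
    (p2 ph0):f1 (p22 ph0):f3
    DN_SEHSQC1
    (p1 ph0):f1 (p21 ph7):f3
    ; t1 bracketed by two equal-sign CTP gradients
    p19:gp14
    d16
    DN_SEHSQC3
    (p2 ph0):f1
    DN_SEHSQC3
    p19:gp14
    d16
    ; PEP back transfer
    (p1 ph0):f1 (p21 ph0):f3
    DN_SEHSQC1
    (p2 ph0):f1 (p22 ph0):f3
    DN_SEHSQC2
    (p1 ph0):f1 (p21 ph0):f3
    DN_SEHSQC2
    (p2 ph0):f1
    p19:gp15
    d16
    goscnp ph22
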