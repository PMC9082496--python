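# 15N HMQC.  CTP selection uses two PFGs bracketing t1 (one in each half),
# each 2.5 ms at 80%, with equal sign so that bulk magnetization evolving in
# either half of t1 is dephased (suppresses wing artifacts in downstream
# modules).  The refocusing gradient g2 matches the bracketing-gradient
# duration and has amplitude +/- n * 8.1% with n = 2, where
# 8.1 = 80 * |gamma(15N)/gamma(1H)| rounded to one decimal place.
abbreviation: M
display_name: 15N HMQC
category: HET_15N
slot: n15
au_program: noah_hmqc
pools:
  required: [N15_BOUND_1H]
  consumed: [N15_BOUND_1H]
  preserved: [BULK_1H, C13_BOUND_1H]
supports_flags: [NUS, PRESAT]
k_scaling: true
use: [p1, p2, p16, p19, p21, d16, cnst4, cnst37, ph0]
parameters:
  - {kind: LOCAL_DELAY, id: DN_HMQC1, definition: "0.5s/cnst4",
     comment: "HMQC defocusing delay, 1/(2 * 1J(NH))"}
  - {kind: LOCAL_DELAY, id: DN_HMQC2, definition: "3u",
     comment: "t1/2 evolution delay (incremented)"}
phase_cycles:
  - {index: 6, steps: [x, -x]}
  - {index: 21, steps: [x, -x], receiver: true}
gradients:
  - {index: 12, amplitude: 80.0, duration: 2.5, shape: SMSQ10.100}
  - {index: 13, amplitude: 16.2, duration: 2.5, shape: SMSQ10.100, echo_antiecho: true}
indirect:
  t1_delay: DN_HMQC2
  echo_antiecho: true
  ea_gradient: 13
body: |2
    ; HMQC defocusing
    (p1 ph0):f1
    DN_HMQC1
    (p21 ph6):f3
    ; t1 bracketed by two equal-sign CTP gradients (duration matches g2)
    p19:gp12
    d16
    DN_HMQC2
    (p2 ph0):f1
    DN_HMQC2
    p19:gp12
    d16
    (p21 ph0):f3
    ; refocusing and CTP selection
    DN_HMQC1
    p19:gp13
    d16
    goscnp ph21
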