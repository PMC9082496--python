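# 13C zz-HMBC module.  Phase cycles and gradient table follow the published
# scheme: phi1 = x,-x; phi2 = x,x,-x,-x; receiver = x,-x,-x,x; all PFGs 1 ms;
# amplitudes g1..g5 = -15, 10, 5, 80, +/-40.2 % of maximum gradient strength.
# The trailing 13C 90 degree pulse after the zz-filter converts residual
# antiphase 1H-13C magnetization into multiple-quantum coherence, which the
# low-pass J-filter then dephases (suppresses one-bond artifacts).
abbreviation: B
display_name: 13C HMBC (zz-filter)
category: HET_13C
slot: hmbc
au_program: noah_hmbc
pools:
  required: [BULK_1H]
  consumed: [BULK_1H]
  # BULK_1H in both sets: partial survival (ASAP mixing / tolerated loss);
  # heteronucleus-bound pools fully preserved in the maximally-retaining variant.
  preserved: [BULK_1H, C13_BOUND_1H, N15_BOUND_1H]
supports_flags: [NUS, PRESAT]
use: [p1, p2, p3, p4, p22, p16, d16, cnst2, cnst4, cnst13, ph0]
parameters:
  - {kind: LOCAL_DELAY, id: DC_HMBC1, definition: "0.5s/cnst13",
     comment: "long-range evolution delay, 1/(2 * nJ(CH))"}
  - {kind: LOCAL_DELAY, id: DC_HMBC2, definition: "0.25s/cnst2",
     comment: "zz-filter half delay, 1/(4 * 1J(CH))"}
  - {kind: LOCAL_DELAY, id: DC_HMBC3, definition: "0.5s/cnst2",
     comment: "low-pass J-filter delay, 1/(2 * 1J(CH))"}
  - {kind: LOCAL_DELAY, id: DC_HMBC4, definition: "3u",
     comment: "t1/2 evolution delay (incremented)"}
  - {kind: LOCAL_DELAY, id: DN_HMBC1, definition: "0.25s/cnst4",
     comment: "15N zz-filter half delay, 1/(4 * 1J(NH))"}
phase_cycles:
  - {index: 1, steps: [x, -x]}
  - {index: 2, steps: [x, x, -x, -x]}
  - {index: 17, steps: [x, -x, -x, x], receiver: true}
gradients:
  - {index: 1, amplitude: -15.0, duration: 1.0, shape: SMSQ10.100}
  - {index: 2, amplitude: 10.0, duration: 1.0, shape: SMSQ10.100}
  - {index: 3, amplitude: 5.0, duration: 1.0, shape: SMSQ10.100}
  - {index: 4, amplitude: 80.0, duration: 1.0, shape: SMSQ10.100}
  - {index: 5, amplitude: 40.2, duration: 1.0, shape: SMSQ10.100, echo_antiecho: true}
indirect:
  t1_delay: DC_HMBC4
  echo_antiecho: true
  ea_gradient: 5
body: |2
  {{ZZ_FILTER}}
    (p3 ph0):f2 ; added 13C 90 pulse after the zz-filter: antiphase -> MQ
    ; two-step low-pass J-filter (dephases one-bond coherences)
    DC_HMBC3
    (p3 ph0):f2
    p16:gp2
    d16
    DC_HMBC3
    (p3 ph0):f2
    p16:gp3
    d16
    ; long-range evolution
    DC_HMBC1
    (p3 ph1):f2
    ; t1 with equal-sign CTP gradients in both halves
    DC_HMBC4
    p16:gp4
    d16
    (p2 ph0):f1
    p16:gp4
    d16
    DC_HMBC4
    (p3 ph2):f2
    DC_HMBC2
    p16:gp5
    d16
    goscnp ph17
variants:
  - label: C_HMBC_A
    retains: []
    block: |
        ; plain excitation: no later module needs satellite-proton magnetization
        (p1 ph0):f1
        p16:gp1
        d16
  - label: C_HMBC_C
    retains: [C13_BOUND_1H]
    block: |
        ; zz-filter: return 13C-bound 1H to +z, excite 12C-bound 1H
        (p1 ph0):f1
        DC_HMBC2
        (p2 ph0):f1 (p4 ph0):f2
        DC_HMBC2
        (p1 ph0):f1
        p16:gp1
        d16
  - label: C_HMBC_N
    retains: [N15_BOUND_1H]
    block: |
        ; zz-filter: return 15N-bound 1H to +z, excite the rest
        (p1 ph0):f1
        DN_HMBC1
        (p2 ph0):f1 (p22 ph0):f3
        DN_HMBC1
        (p1 ph0):f1
        p16:gp1
        d16
  - label: C_HMBC_CN
    retains: [C13_BOUND_1H, N15_BOUND_1H]
    block: |
        ; double zz-filter: return both 13C- and 15N-bound 1H to +z
        (p1 ph0):f1
        DC_HMBC2
        (p2 ph0):f1 (p4 ph0):f2
        DC_HMBC2
        (p1 ph0):f1
        p16:gp1
        d16
        (p1 ph0):f1
        DN_HMBC1
        (p2 ph0):f1 (p22 ph0):f3
        DN_HMBC1
        (p1 ph0):f1
        p16:gp1
        d16
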