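# Magnitude-mode 2DJ ("Jqf"): plain spin-echo J-resolved module.
abbreviation: Jqf
display_name: magnitude-mode 2DJ (Jqf)
category: PURESHIFT_2DJ
slot: h1
au_program: noah_jres
pools:
  required: [BULK_1H]
  consumed: [BULK_1H, C13_BOUND_1H, N15_BOUND_1H]
  preserved: []
supports_flags: [NUS, PRESAT]
k_scaling: true
use: [p1, p2, p16, d16, cnst37, ph0]
parameters:
  - {kind: LOCAL_DELAY, id: DH_QFJRES1, definition: "3u",
     comment: "t1/2 J-evolution delay (incremented)"}
phase_cycles:
  - {index: 16, steps: [x, -x]}
  - {index: 31, steps: [x, -x], receiver: true}
gradients:
  - {index: 31, amplitude: 25.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DH_QFJRES1
body: |2
    (p1 ph16):f1
    DH_QFJRES1
    p16:gp31
    d16
    (p2 ph0):f1
    p16:gp31
    d16
    DH_QFJRES1
    goscnp ph31
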