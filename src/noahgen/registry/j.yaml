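# PSYCHE 2DJ: J-resolved spectroscopy with pure absorption-mode line shapes.
abbreviation: J
display_name: PSYCHE 2DJ
category: PURESHIFT_2DJ
slot: h1
au_program: noah_jres
pools:
  required: [BULK_1H]
  consumed: [BULK_1H, C13_BOUND_1H, N15_BOUND_1H]
  preserved: []
supports_flags: [NUS, PRESAT]
k_scaling: true
sapphire: true
use: [p1, p2, p16, p40, d16, cnst20, cnst37, cnst38, ph0, sp40]
parameters:
  - {kind: LOCAL_DELAY, id: DH_JRES1, definition: "3u",
     comment: "t1/2 J-evolution delay (incremented)"}
phase_cycles:
  - {index: 15, steps: [x, -x]}
  - {index: 30, steps: [x, -x], receiver: true}
gradients:
  - {index: 25, amplitude: 1.7, duration: 30.0, shape: SMSQ10.100}
  - {index: 28, amplitude: 35.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DH_JRES1
body: |2
    (p1 ph15):f1
    DH_JRES1
    ; PSYCHE element in the J-refocusing position
    p16:gp28
    d16
    p16:gp25
    (p40:sp40 ph0):f1
    p16:gp28
    d16
    DH_JRES1
    goscnp ph30
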