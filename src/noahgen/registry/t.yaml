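# TOCSY with DIPSI-2 isotropic mixing.
abbreviation: T
display_name: TOCSY
category: HOMONUCLEAR
slot: h1
au_program: noah_tocsy
pools:
  required: [BULK_1H]
  consumed: [BULK_1H, C13_BOUND_1H, N15_BOUND_1H]
  preserved: [BULK_1H]
supports_flags: [ES, NUS, PRESAT]
use: [p1, p2, p6, p12, p16, d9, d16, ph0, gpz29, sp1]
parameters:
  - {kind: LOCAL_DELAY, id: DH_TOCSY1, definition: "3u",
     comment: "t1 evolution delay (incremented)"}
phase_cycles:
  - {index: 10, steps: [x, -x]}
  - {index: 25, steps: [x, -x], receiver: true}
gradients:
  - {index: 18, amplitude: 35.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DH_TOCSY1
body: |2
    (p1 ph10):f1
    DH_TOCSY1
    ; DIPSI-2 isotropic mixing, total duration d9
    p16:gp18
    d16
    (p6 ph0):f1
    d9
    p16:gp18
    d16
  {{ES}}
    goscnp ph25
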