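# Gradient-selected COSY.  Draws on bulk 1H; nonselective, so it consumes
# all three pools, but enough bulk magnetization survives (and ASAP mixing
# can replenish it) that one further homonuclear module is tolerated.
abbreviation: C
display_name: COSY
category: HOMONUCLEAR
slot: h1
au_program: noah_cosy
pools:
  required: [BULK_1H]
  consumed: [BULK_1H, C13_BOUND_1H, N15_BOUND_1H]
  preserved: [BULK_1H]
supports_flags: [ES, NUS, PRESAT]
use: [p1, p2, p12, p16, d16, ph0, gpz29, sp1]
parameters:
  - {kind: LOCAL_DELAY, id: DH_COSY1, definition: "3u",
     comment: "t1 evolution delay (incremented)"}
phase_cycles:
  - {index: 8, steps: [x, -x]}
  - {index: 23, steps: [x, -x], receiver: true}
gradients:
  - {index: 16, amplitude: 30.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DH_COSY1
body: |2
    (p1 ph8):f1
    DH_COSY1
    p16:gp16
    d16
    (p1 ph0):f1
    p16:gp16
    d16
  {{ES}}
    goscnp ph23
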