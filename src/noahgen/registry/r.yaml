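# ROESY with CW spin lock.  Like NOESY, nothing usable survives the mixing.
abbreviation: R
display_name: ROESY
category: HOMONUCLEAR
slot: h1
au_program: noah_roesy
pools:
  required: [BULK_1H]
  consumed: [BULK_1H, C13_BOUND_1H, N15_BOUND_1H]
  preserved: []
supports_flags: [ES, NUS, PRESAT]
use: [p1, p2, p12, p16, d16, ph0, gpz29, sp1]
parameters:
  - {kind: PULSE, id: 15, definition: "", comment: "ROESY CW spin-lock pulse"}
  - {kind: LOCAL_DELAY, id: DH_ROESY1, definition: "3u",
     comment: "t1 evolution delay (incremented)"}
phase_cycles:
  - {index: 12, steps: [x, -x]}
  - {index: 27, steps: [x, -x], receiver: true}
gradients:
  - {index: 20, amplitude: 37.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DH_ROESY1
body: |2
    (p1 ph12):f1
    DH_ROESY1
    ; CW spin lock (ROE mixing)
    (p15 ph0):f1
    p16:gp20
    d16
  {{ES}}
    goscnp ph27
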