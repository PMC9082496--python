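# NOESY.  The long mixing time scrambles whatever magnetization remains, so
# no pool is preserved; NOESY therefore ends the homonuclear tail.  With the
# PRESAT flag, presaturation is applied during the mixing time as well as
# the recovery delay.
abbreviation: N
display_name: NOESY
category: HOMONUCLEAR
slot: h1
au_program: noah_noesy
pools:
  required: [BULK_1H]
  consumed: [BULK_1H, C13_BOUND_1H, N15_BOUND_1H]
  preserved: []
supports_flags: [ES, ZQS, NUS, PRESAT]
use: [p1, p2, p12, p16, p32, d16, ph0, gpz29, gpz0, sp1, sp29]
parameters:
  - {kind: DELAY, id: 8, definition: "", comment: "NOESY mixing time"}
  - {kind: LOCAL_DELAY, id: DH_NOESY1, definition: "3u",
     comment: "t1 evolution delay (incremented)"}
phase_cycles:
  - {index: 11, steps: [x, -x]}
  - {index: 26, steps: [x, -x], receiver: true}
gradients:
  - {index: 19, amplitude: 40.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DH_NOESY1
body: |2
    (p1 ph11):f1
    DH_NOESY1
    (p1 ph0):f1
    ; NOE mixing time (presaturated when -DPRESAT is set)
  #ifdef PRESAT
    d8 cw:f1
    4u do:f1
  #else
    d8
  #endif
    p16:gp19
    d16
    (p1 ph0):f1
  {{ZQS}}
  {{ES}}
    goscnp ph26
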