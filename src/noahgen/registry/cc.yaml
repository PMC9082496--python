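# CLIP-COSY ("Cc"): in-phase COSY via perfect-echo mixing, well suited to
# ASAP acceleration.
abbreviation: Cc
display_name: CLIP-COSY (Cc)
category: HOMONUCLEAR
slot: h1
au_program: noah_clipcosy
pools:
  required: [BULK_1H]
  consumed: [BULK_1H, C13_BOUND_1H, N15_BOUND_1H]
  preserved: [BULK_1H]
supports_flags: [ES, ZQS, NUS, PRESAT]
use: [p1, p2, p12, p16, p32, d16, ph0, gpz29, gpz0, sp1, sp29]
parameters:
  - {kind: CONSTANT, id: 14, definition: "",
     comment: "= J(HH) for in-phase (perfect echo) mixing [Hz]"}
  - {kind: LOCAL_DELAY, id: DH_CLIP1, definition: "0.25s/cnst14",
     comment: "perfect-echo mixing delay, 1/(4 * J(HH))"}
  - {kind: LOCAL_DELAY, id: DH_CLIP2, definition: "3u",
     comment: "t1 evolution delay (incremented)"}
phase_cycles:
  - {index: 9, steps: [x, -x]}
  - {index: 24, steps: [x, -x], receiver: true}
gradients:
  - {index: 17, amplitude: 45.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DH_CLIP2
body: |2
    (p1 ph9):f1
    DH_CLIP2
    (p1 ph0):f1
    ; perfect-echo in-phase mixing
    DH_CLIP1
    (p2 ph0):f1
    DH_CLIP1
    (p1 ph0):f1
    DH_CLIP1
    (p2 ph0):f1
    DH_CLIP1
    p16:gp17
    d16
    (p1 ph0):f1
  {{ZQS}}
  {{ES}}
    goscnp ph24
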