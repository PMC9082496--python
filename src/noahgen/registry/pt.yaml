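# TSE-PSYCHE ("PT"): triple-spin-echo variant, more robust toward strong
# coupling than plain PSYCHE.
abbreviation: Pt
display_name: TSE-PSYCHE pure shift (PT)
category: PURESHIFT_2DJ
slot: h1
au_program: noah_psyche
pools:
  required: [BULK_1H]
  consumed: [BULK_1H, C13_BOUND_1H, N15_BOUND_1H]
  preserved: []
supports_flags: [NUS, PRESAT]
k_scaling: true
sapphire: true
use: [p1, p2, p16, p40, p41, d16, cnst20, cnst37, cnst38, ph0, sp40, sp41]
parameters:
  - {kind: LOCAL_DELAY, id: DH_TPSYCHE1, definition: "3u",
     comment: "chunk evolution half delay (incremented)"}
phase_cycles:
  - {index: 14, steps: [x, -x]}
  - {index: 29, steps: [x, -x], receiver: true}
gradients:
  - {index: 23, amplitude: 1.7, duration: 30.0, shape: SMSQ10.100}
  - {index: 24, amplitude: 35.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DH_TPSYCHE1
body: |2
    (p1 ph14):f1
    DH_TPSYCHE1
    ; triple spin echo: chirp - saltire - chirp, weak PFG under the saltire
    p16:gp24
    d16
    (p41:sp41 ph0):f1
    p16:gp23
    (p40:sp40 ph0):f1
    (p41:sp41 ph0):f1
    p16:gp24
    d16
    DH_TPSYCHE1
    goscnp ph29
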