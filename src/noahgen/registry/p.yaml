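# Pseudo-2D PSYCHE pure shift module.  The indirect dimension holds data
# chunks rather than a chemical-shift axis (16-32 increments suffice), so
# k-scaling trades increments for transients and SAPPHIRE averaging uses the
# extra transients to suppress J-modulation sidebands.  Low saltire flip
# angles (cnst20, 10-15 degrees) maximize spectral purity; the transient
# surplus inherent to NOAH acquisition compensates the sensitivity cost.
abbreviation: P
display_name: pseudo-2D PSYCHE pure shift
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
use: [p1, p2, p16, p40, d16, cnst20, cnst37, cnst38, ph0, sp40]
parameters:
  - {kind: LOCAL_DELAY, id: DH_PSYCHE1, definition: "3u",
     comment: "chunk evolution half delay (incremented)"}
phase_cycles:
  - {index: 13, steps: [x, -x]}
  - {index: 28, steps: [x, -x], receiver: true}
gradients:
  - {index: 21, amplitude: 1.7, duration: 30.0, shape: SMSQ10.100}
  - {index: 22, amplitude: 35.0, duration: 1.0, shape: SMSQ10.100}
indirect:
  t1_delay: DH_PSYCHE1
body: |2
    (p1 ph13):f1
    DH_PSYCHE1
    ; PSYCHE J-refocusing element: saltire pair under a weak PFG
    p16:gp22
    d16
    p16:gp21
    (p40:sp40 ph0):f1
    p16:gp22
    d16
    DH_PSYCHE1
    goscnp ph28
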