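# Shared registry entries.  Modules pull these in via their `use:` list so
# that parameters standardized across the whole library (hard pulse widths,
# coupling-constant slots, the gradient recovery delay, ...) have exactly one
# definition, which also guarantees duplicate entries merge at collation.

parameters:
  p1:     {kind: PULSE, id: 1,  comment: "f1 channel - 90 degree high power pulse"}
  p2:     {kind: PULSE, id: 2,  comment: "f1 channel - 180 degree high power pulse"}
  p3:     {kind: PULSE, id: 3,  comment: "f2 channel - 90 degree high power pulse (13C)"}
  p4:     {kind: PULSE, id: 4,  comment: "f2 channel - 180 degree high power pulse (13C)"}
  p6:     {kind: PULSE, id: 6,  comment: "f1 channel - 90 degree low power pulse (isotropic mixing)"}
  p12:    {kind: PULSE, id: 12, comment: "f1 channel - 180 degree shaped pulse (excitation sculpting)"}
  p16:    {kind: PULSE, id: 16, comment: "homospoil/gradient pulse [1 ms]"}
  p19:    {kind: PULSE, id: 19, comment: "t1-bracketing CTP gradient pulse [2.5 ms]"}
  p21:    {kind: PULSE, id: 21, comment: "f3 channel - 90 degree high power pulse (15N)"}
  p22:    {kind: PULSE, id: 22, comment: "f3 channel - 180 degree high power pulse (15N)"}
  p32:    {kind: PULSE, id: 32, comment: "f1 channel - swept-frequency 180 degree pulse (ZQS)"}
  p40:    {kind: PULSE, id: 40, comment: "f1 channel - saltire chirp pulse (PSYCHE element)"}
  p41:    {kind: PULSE, id: 41, comment: "f1 channel - chirp inversion pulse (TSE-PSYCHE)"}
  d9:     {kind: DELAY, id: 9,  comment: "TOCSY mixing time"}
  d16:    {kind: DELAY, id: 16, comment: "delay for gradient recovery [200 us]"}
  cnst2:  {kind: CONSTANT, id: 2,  comment: "= 1J(CH)  [Hz]"}
  cnst4:  {kind: CONSTANT, id: 4,  comment: "= 1J(NH)  [Hz]"}
  cnst13: {kind: CONSTANT, id: 13, comment: "= nJ(CH) long-range coupling [Hz]"}
  cnst20: {kind: CONSTANT, id: 20, comment: "PSYCHE saltire flip angle [degrees, typically 10-15]"}
  cnst37: {kind: CONSTANT, id: 37, comment: "k-scaling factor: t1 increments traded for transients"}
  cnst38: {kind: CONSTANT, id: 38, comment: "SAPPHIRE averaging steps per increment [8]"}

phase_cycles:
  - {index: 0, steps: [x]}

gradients:
  # gpz29: excitation sculpting echo pair; gpz0: weak PFG under the ZQS chirp
  - {index: 29, amplitude: 31.0, duration: 1.0, shape: SMSQ10.100}
  - {index: 0,  amplitude: 11.0, duration: 1.0, shape: SMSQ10.100}

shaped_pulses:
  - {name: sp1,  pulse: p12, directive: "wu180H1_sculpt: Sinc1.1000(2 ms)"}
  - {name: sp29, pulse: p32, directive: "zqs_chirp: Crp_zqf.20(20 ms, 10 kHz)"}
  - {name: sp40, pulse: p40, directive: "psyche_saltire: saltire.30(30 ms, 10 kHz; flip cnst20)"}
  - {name: sp41, pulse: p41, directive: "tse_chirp: Crp.30(30 ms, 10 kHz)"}

blocks:
  ES: |
    #ifdef ES
      ; excitation sculpting: double PFG spin echo, shaped + hard 180
      p16:gp29
      d16
      (p12:sp1 ph0):f1
      (p2 ph0):f1
      p16:gp29
      d16
    #endif
  ZQS: |
    #ifdef ZQS
      ; zero-quantum suppression: swept-frequency 180 under a weak PFG
      10u
      (p32:sp29 ph0):f1
      p16:gp0
      d16
    #endif
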