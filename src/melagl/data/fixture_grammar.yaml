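# Fixture finite-state melody grammar.
#
# A documented stand-in machine with the structural properties the stimulus
# pipeline requires: 8 terminal tone pairs (a-h) over 8 pitches spanning one
# octave, an upper and a lower pathway that share only the start and accept
# regions, and bounded loops so that enumeration to 15 terminal pairs yields
# well over 33 distinct sequences of 8-30 tones.  This machine is synthetic:
# it is not a reconstruction of any previously published grammar.
states: [S0, U1, U2, U3, L1, L2, L3, F]
start: S0
accepts: [F]
transitions:
  - [S0, a, U1]
  - [U1, c, U2]
  - [U2, d, U2]
  - [U2, e, U3]
  - [U3, f, U1]
  - [U3, g, F]
  - [S0, b, L1]
  - [L1, d, L2]
  - [L2, c, L2]
  - [L2, f, L3]
  - [L3, e, L1]
  - [L3, h, F]
pathways:
  upper: [U1, U2, U3]
  lower: [L1, L2, L3]
  shared: [S0, F]
# Tone pairs over the 8-pitch source set (span one octave).  Pairs favor
# steps, thirds and fourths so the untransformed surface is genuinely
# consistent with common melodic expectancy (the identity mapping ranks at
# the top of the consistency ranking over random re-voicings).
terminals:
  a: [69, 72]
  b: [60, 65]
  c: [65, 67]
  d: [72, 69]
  e: [71, 67]
  f: [64, 65]
  g: [67, 71]
  h: [62, 67]
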