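# Roster completion: item strings (and optionally deviant positions) for
# the five sequences the package does not hard-code.  These entries equal
# the bundled synthetic stand-ins; replace them to analyze other stimuli.
sequences:
  Shrinking:
    items: AAAABBAABBABABAB
  "Pairs&Alt.2":
    items: AABBABABABABAABB
  ThreeTwo:
    items: AAABBBAABBAAABBB
  CenterMirror:
    items: AABABBABBABBABAA
  Complex:
    items: AAABAAABBABAAABA
    deviant_positions: [9, 12, 13, 14]
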