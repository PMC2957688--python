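# Sex-averaged genetic lengths of the human autosomes (cM), deCODE-style.
# Used as the default L_autosome and as the chromosome lengths for the
# autozygous-segment simulator when no reference map is supplied.
autosome_lengths_cm:
  1: 270.3
  2: 257.4
  3: 222.0
  4: 206.1
  5: 202.3
  6: 189.4
  7: 184.1
  8: 165.5
  9: 160.1
  10: 174.1
  11: 152.5
  12: 167.1
  13: 129.1
  14: 122.2
  15: 128.5
  16: 128.0
  17: 135.0
  18: 121.3
  19: 106.2
  20: 100.6
  21: 62.8
  22: 70.1
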