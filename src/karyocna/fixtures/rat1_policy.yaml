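# Resolution of the uncertain ('?') breakpoint bands occurring in the
# Rat-1 karyotype, onto band ranges of the packaged synthetic rn5-like
# cytoband map.  Unlisted uncertain bands fall back to the widest band
# group matching the certain digits.
fallback: widest_band_group
resolutions:
  "2q?2": [q22, q25]
  "3q?22": [q22, q22]
  "10q?3": ["q32.1", "q32.1"]
  "12q1?2": [q12, q12]
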