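# Example region-configuration table (YAML flavour).
#
# One record per (family, helix): 1-based inclusive alignment columns of
# the predicted transmembrane window plus the reference column numbered
# x.50. The CSV flavour has the same fields as a header row. Transmembrane
# windows come from external structural analysis and are user-supplied.
- family_id: classA
  helix_id: TM1
  start_col: 9
  end_col: 33
  ref50_col: 21
- family_id: classB
  helix_id: TM1
  start_col: 9
  end_col: 33
  ref50_col: 21
- family_id: bridge
  helix_id: TM1
  start_col: 9
  end_col: 33
  ref50_col: 21
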