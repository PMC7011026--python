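# Default treatment sequences (first line -> second line -> third line).
# Sequences are data: users may define their own files with the same schema.
sequences:
  pth_tdm1_tl:
    label: "PTH -> T-DM1 -> trastuzumab+lapatinib"
    lines: [pth, tdm1, tras_lap]
  pth_lx_tc:
    label: "PTH -> lapatinib+capecitabine -> trastuzumab+capecitabine"
    lines: [pth, lap_cap, tras_cap]
  th_tdm1_tl:
    label: "TH -> T-DM1 -> trastuzumab+lapatinib"
    lines: [th, tdm1, tras_lap]
  th_lx_tc:
    label: "TH -> lapatinib+capecitabine -> trastuzumab+capecitabine"
    lines: [th, lap_cap, tras_cap]
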