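# Regimen schedules expanded as weekly cost patterns.  Each component charges
# the named acquisition-cost parameter on the weeks its patterns generate
# (week 1 = first treatment week of the line).  Patterns: {start} alone is a
# single week; {start, period} recurs every `period` weeks; `until` bounds the
# run (inclusive).
#
# The administration weeks encode the published schedule verbatim, including
# its quirks: the post-docetaxel phase of PTH/TH runs 17,20,23,... (shifted by
# one week relative to the 1,4,...,16 docetaxel phase), and the
# trastuzumab+capecitabine schedule charges the loading-dose price on weeks
# 3,6,9,... alongside the maintenance price on weeks 4,7,10,...
regimens:
  pth:
    label: "Pertuzumab + trastuzumab + docetaxel"
    her2_targeted: true
    components:
      - param: docetaxel
        weeks: [{start: 1, period: 3, until: 16}]
      - param: pegfilgrastim
        weeks: [{start: 1, period: 3, until: 16}]
      - param: trastuzumab_loading
        weeks: [{start: 1}]
      - param: trastuzumab_maintenance
        weeks: [{start: 4, period: 3, until: 16}, {start: 17, period: 3}]
      - param: pertuzumab_loading
        weeks: [{start: 1}]
      - param: pertuzumab_maintenance
        weeks: [{start: 4, period: 3, until: 16}, {start: 17, period: 3}]
  th:
    label: "Trastuzumab + docetaxel"
    her2_targeted: true
    components:
      - param: docetaxel
        weeks: [{start: 1, period: 3, until: 16}]
      - param: trastuzumab_loading
        weeks: [{start: 1}]
      - param: trastuzumab_maintenance
        weeks: [{start: 4, period: 3, until: 16}, {start: 17, period: 3}]
  tdm1:
    label: "Trastuzumab emtansine (T-DM1)"
    her2_targeted: true
    components:
      - param: tdm1
        weeks: [{start: 1, period: 3}]
  lap_cap:
    label: "Lapatinib + capecitabine"
    her2_targeted: true
    components:
      - param: lapatinib_weekly
        weeks: [{start: 1, period: 1}]
      - param: capecitabine_weekly
        weeks: [{start: 1, period: 3}, {start: 2, period: 3}]
  tras_lap:
    label: "Trastuzumab + lapatinib"
    her2_targeted: true
    components:
      - param: trastuzumab_loading
        weeks: [{start: 1}]
      - param: trastuzumab_maintenance
        weeks: [{start: 4, period: 3}]
      - param: lapatinib_weekly
        weeks: [{start: 1, period: 1}]
  tras_cap:
    label: "Trastuzumab + capecitabine"
    her2_targeted: true
    components:
      - param: trastuzumab_loading
        weeks: [{start: 1}, {start: 3, period: 3}]
      - param: trastuzumab_maintenance
        weeks: [{start: 4, period: 3}]
      - param: capecitabine_weekly
        weeks: [{start: 1, period: 3}, {start: 2, period: 3}]
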