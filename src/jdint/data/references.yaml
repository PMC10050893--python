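# Default reference-protein annotations for the Josephin-domain baits.
#
# wt/exp ataxin-3 coordinates follow the standard annotation of the most
# common brain isoform: JD 1-180, UIMs 224-243 / 244-263 / 331-349, polyQ
# 292-305 (14Q).  The expanded form carries 50Q; its polyQ span (292-341)
# and the +36 shift of downstream annotations are derived from the wt span.
# NES spans are approximate figure-style metadata.  JOSD1/JOSD2/JosL lengths
# and JD spans are editable defaults, not assertions.
references:
  - id: wt_atxn3
    form: wt
    length: 361
    polyq: {start: 292, end: 305, length: 14}
    domains:
      - {name: JD, start: 1, end: 180}
      - {name: NES77, start: 77, end: 87}
      - {name: NES141, start: 141, end: 158}
      - {name: UIM1, start: 224, end: 243}
      - {name: UIM2, start: 244, end: 263}
      - {name: polyQ, start: 292, end: 305}
      - {name: UIM3, start: 331, end: 349}
  - id: exp_atxn3
    form: exp
    length: 397
    polyq: {start: 292, end: 341, length: 50}
    domains:
      - {name: JD, start: 1, end: 180}
      - {name: NES77, start: 77, end: 87}
      - {name: NES141, start: 141, end: 158}
      - {name: UIM1, start: 224, end: 243}
      - {name: UIM2, start: 244, end: 263}
      - {name: polyQ, start: 292, end: 341}
      - {name: UIM3, start: 367, end: 385}
  - id: josl
    form: single-domain
    length: 236
    domains:
      - {name: JD, start: 1, end: 180}
  - id: josd1
    form: single-domain
    length: 202
    domains:
      - {name: JD, start: 1, end: 180}
  - id: josd2
    form: single-domain
    length: 188
    domains:
      - {name: JD, start: 1, end: 180}
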