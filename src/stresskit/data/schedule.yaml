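# Default experimental stage schedule, seconds from recording start.
# 5-min baseline rest, 5-min anticipation, 10-min improvisation stress task,
# 5-min intermediate rest, 5-min sound intervention, then two 5-min rests.
stages:
  - {label: baseline, start_s: 0, end_s: 300}
  - {label: anticipation, start_s: 300, end_s: 600}
  - {label: stress, start_s: 600, end_s: 1200}
  - {label: intermediate, start_s: 1200, end_s: 1500}
  - {label: sound, start_s: 1500, end_s: 1800}
  - {label: rest1, start_s: 1800, end_s: 2100}
  - {label: rest2, start_s: 2100, end_s: 2400}
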