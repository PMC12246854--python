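# 2 x 12-channel prefrontal montage (24 optodes), symmetric over the left and
# right frontal areas, covering Brodmann areas 9, 10, 44, 45, 46 and 47.
# Hemisphere / Brodmann labels for channels that appear in reported
# comparisons are taken from the published channel tables; the remaining
# channels are filled in mirror-symmetrically with plausible labels to
# complete the 2 x 12 grid (partially reconstructed -- see docs/methods.md).
# Laterality pairs are listed as (right_channel, left_channel).
source_detector_distance_cm: 3.0
channels:
  # right hemisphere
  - {id: Tx1-Rx1, hemisphere: right, brodmann_area: 10}
  - {id: Tx1-Rx2, hemisphere: right, brodmann_area: 46}
  - {id: Tx2-Rx2, hemisphere: right, brodmann_area: 44}
  - {id: Tx2-Rx3, hemisphere: right, brodmann_area: 9}
  - {id: Tx3-Rx1, hemisphere: right, brodmann_area: 46}
  - {id: Tx3-Rx2, hemisphere: right, brodmann_area: 45}
  - {id: Tx3-Rx3, hemisphere: right, brodmann_area: 9}
  - {id: Tx3-Rx4, hemisphere: right, brodmann_area: 45}
  - {id: Tx4-Rx3, hemisphere: right, brodmann_area: 47}
  - {id: Tx4-Rx4, hemisphere: right, brodmann_area: 47}
  - {id: Tx5-Rx3, hemisphere: right, brodmann_area: 10}
  - {id: Tx5-Rx4, hemisphere: right, brodmann_area: 10}
  # left hemisphere
  - {id: Tx6-Rx5, hemisphere: left, brodmann_area: 10}
  - {id: Tx6-Rx6, hemisphere: left, brodmann_area: 9}
  - {id: Tx7-Rx6, hemisphere: left, brodmann_area: 46}
  - {id: Tx7-Rx7, hemisphere: left, brodmann_area: 44}
  - {id: Tx8-Rx5, hemisphere: left, brodmann_area: 46}
  - {id: Tx8-Rx7, hemisphere: left, brodmann_area: 45}
  - {id: Tx8-Rx8, hemisphere: left, brodmann_area: 45}
  - {id: Tx9-Rx6, hemisphere: left, brodmann_area: 10}
  - {id: Tx9-Rx7, hemisphere: left, brodmann_area: 9}
  - {id: Tx9-Rx8, hemisphere: left, brodmann_area: 10}
  - {id: Tx10-Rx7, hemisphere: left, brodmann_area: 44}
  - {id: Tx10-Rx8, hemisphere: left, brodmann_area: 47}
pairs:
  - [Tx5-Rx4, Tx9-Rx8]
  - [Tx5-Rx3, Tx9-Rx6]
  - [Tx3-Rx1, Tx8-Rx5]
  - [Tx3-Rx2, Tx8-Rx7]
  - [Tx2-Rx3, Tx6-Rx6]
  - [Tx4-Rx4, Tx10-Rx8]
  - [Tx3-Rx4, Tx8-Rx8]
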