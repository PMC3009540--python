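# Default synthetic benchmark sweep: purity 10%-100% for the
# hydrophobic+charged implant, with and without false-positive removal,
# plus the two full-purity chemistry conditions.
# 3 replicates keep the sweep fast; set replicates: 10 for the full protocol.
replicates: 3
n_pos: 219
n_neg: 220
length: 200
seed: 1
conditions:
  - {name: hydrophobic_100, flank: hydrophobic, true_ratio: 1.0, removal: false}
  - {name: hc_100, flank: hydrophobic+charged, true_ratio: 1.0, removal: false}
  - {name: hc_80, flank: hydrophobic+charged, true_ratio: 0.8, removal: false}
  - {name: hc_60, flank: hydrophobic+charged, true_ratio: 0.6, removal: false}
  - {name: hc_40, flank: hydrophobic+charged, true_ratio: 0.4, removal: false}
  - {name: hc_20, flank: hydrophobic+charged, true_ratio: 0.2, removal: false}
  - {name: hc_10, flank: hydrophobic+charged, true_ratio: 0.1, removal: false}
  - {name: hc_100_rm, flank: hydrophobic+charged, true_ratio: 1.0, removal: true}
  - {name: hc_80_rm, flank: hydrophobic+charged, true_ratio: 0.8, removal: true}
  - {name: hc_60_rm, flank: hydrophobic+charged, true_ratio: 0.6, removal: true}
  - {name: hc_40_rm, flank: hydrophobic+charged, true_ratio: 0.4, removal: true}
  - {name: hc_20_rm, flank: hydrophobic+charged, true_ratio: 0.2, removal: true}
  - {name: hc_10_rm, flank: hydrophobic+charged, true_ratio: 0.1, removal: true}
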