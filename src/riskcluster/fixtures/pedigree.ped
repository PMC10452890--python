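# Synthetic pedigree mirroring the study family's sequenced structure:
# 4 generations, 13 sequenced members stratifying 3 HRLS / 4 IRLS / 6 LRLS.
# Columns: family subject father mother sex affection [sequenced]
FAM1 I1 0 0 1 2
FAM1 I2 0 0 2 1
FAM1 II1 I1 I2 2 2 1
FAM1 II2 0 0 1 1
FAM1 II3 I1 I2 1 2
FAM1 II4 0 0 2 1
FAM1 II5 I1 I2 2 1
FAM1 II6 0 0 1 1
FAM1 III1 II2 II1 2 2 1
FAM1 III2 II2 II1 2 1 1
FAM1 III3 II2 II1 2 1 1
FAM1 III4 II3 II4 1 2 1
FAM1 III5 II3 II4 2 1 1
FAM1 III6 II3 II4 2 1 1
FAM1 III7 II6 II5 1 1 1
FAM1 III8 II6 II5 2 1 1
FAM1 III9 0 0 2 1
FAM1 III10 0 0 1 1
FAM1 IV1 III7 III9 1 1 1
FAM1 IV2 III7 III9 2 1 1
FAM1 IV3 III10 III8 1 1 1
FAM1 IV4 III10 III8 2 1 1
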