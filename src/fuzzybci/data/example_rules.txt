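# Example fuzzy rule base for visuospatial-attention decoding.
#
# Variable ids follow {electrode}_{band}_{feature}_{window_ms}; the
# typographic form P8_T_ERS"300 seen in print normalizes to P8_T_ERS2_300.
# Labels: 1 = audio attention with passive view, 2 = forming cognitive
# maps, 3 = visuospatial traversing.
#
# Core rules:
IF T7_A_ERS2_300 is high THEN label 1
IF T7_T_ERS2_300 is high AND P7_T_ERS2_300 is high THEN label 1
IF T7_BH_ERS2_250 is high AND T8_BH_ERS2_250 is high THEN label 1
IF P8_T_ERS2_300 is high AND T8_G_ERS2_250 is high THEN label 1
IF T8_T_ERS2_250 is high AND T8_G_ERS2_250 is high THEN label 2
# Frontal-theta valence example (score consequent on a [0, 1] scale):
IF F4_T_ERS2_300 is high AND O2_T_ERS2_300 is high AND P8_T_ERS2_300 is high THEN value 0.1
# Documented placeholders sketching the remainder of a full rule base:
IF T8_BH_ERS2_250 is high THEN label 1
IF P8_G_ERS2_250 is high THEN label 3
IF F7_G_ERS2_250 is high THEN label 1
IF F8_T_ERS2_300 is high THEN label 1
IF T7_T_ERS2_300 is high THEN label 1
IF T8_T_ERS2_300 is high THEN label 1
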