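# Synthetic example MIC distribution for teicoplanin vs MRSA.
# Constructed to resemble the qualitative shape of surveillance
# distributions (mode 0.5 mg/L, wild type <= 2 mg/L); NOT surveillance
# data.  Replace with a real frequency table for substantive CFR work.
mic_mg_per_L,frequency
0.032,0.0
0.064,0.0
0.125,0.002
0.25,0.075
0.5,0.46
1,0.39
2,0.062
4,0.008
8,0.002
16,0.001
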