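marker,sw_pc1,sw_pc2
LAI,High,Low
SD_AB,High,High
SD_AD,High,High
TD_AB,High,High
TD_AD,High,Low
WUE,High,Low
CTD,High,High
MDA,Low,High
CAR,High,Low
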