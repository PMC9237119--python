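marker,genotype,treatment,pair,r,label,stars,source
SOD,TJ2049,control,V3_vs_R5,0.62,S,***,Table 1
SOD,TJ2049,control,vs_yield,-0.12,,ns,Table 1
SOD,TJ2049,stress,V3_vs_R5,0.93,S,***,Table 1
SOD,TJ2049,stress,vs_yield,0.17,,ns,Table 1
SOD,MUNASQA,control,V3_vs_R5,0.97,S,***,Table 1
SOD,MUNASQA,control,vs_yield,-0.04,,ns,Table 1
SOD,MUNASQA,stress,V3_vs_R5,0.96,S,***,Table 1
SOD,MUNASQA,stress,vs_yield,0.1,,ns,Table 1
APX,TJ2049,control,V3_vs_R5,0.9,S,***,Table 1
APX,TJ2049,control,vs_yield,0.29,W,*,Table 1
APX,TJ2049,stress,V3_vs_R5,0.94,S,***,Table 1
APX,TJ2049,stress,vs_yield,0.21,,ns,Table 1
APX,MUNASQA,control,V3_vs_R5,0.97,S,***,Table 1
APX,MUNASQA,control,vs_yield,0.25,,ns,Table 1
APX,MUNASQA,stress,V3_vs_R5,0.95,S,***,Table 1
APX,MUNASQA,stress,vs_yield,0.7,S,***,Table 1
POX,TJ2049,control,V3_vs_R5,0.93,S,***,Table 1
POX,TJ2049,control,vs_yield,0.6,S,***,Table 1
POX,TJ2049,stress,V3_vs_R5,0.97,S,***,Table 1
POX,TJ2049,stress,vs_yield,0.34,W,**,Table 1
POX,MUNASQA,control,V3_vs_R5,0.96,S,***,Table 1
POX,MUNASQA,control,vs_yield,0.39,W,***,Table 1
POX,MUNASQA,stress,V3_vs_R5,0.94,S,***,Table 1
POX,MUNASQA,stress,vs_yield,0.27,W,*,Table 1
CAT,TJ2049,control,V3_vs_R5,0.95,S,***,Table 1
CAT,TJ2049,control,vs_yield,0.72,S,***,Table 1
CAT,TJ2049,stress,V3_vs_R5,0.93,S,***,Table 1
CAT,TJ2049,stress,vs_yield,0.46,W,***,Table 1
CAT,MUNASQA,control,V3_vs_R5,0.88,S,***,Table 1
CAT,MUNASQA,control,vs_yield,0.49,W,***,Table 1
CAT,MUNASQA,stress,V3_vs_R5,0.9,S,***,Table 1
CAT,MUNASQA,stress,vs_yield,0.86,S,***,Table 1
PRO,TJ2049,control,V3_vs_R5,0.12,,ns,Table 1
PRO,TJ2049,control,vs_yield,0.73,S,***,Table 1
PRO,TJ2049,stress,V3_vs_R5,0.96,S,***,Table 1
PRO,TJ2049,stress,vs_yield,0.47,W,***,Table 1
PRO,MUNASQA,control,V3_vs_R5,0.92,S,***,Table 1
PRO,MUNASQA,control,vs_yield,0.81,S,***,Table 1
PRO,MUNASQA,stress,V3_vs_R5,0.94,S,***,Table 1
PRO,MUNASQA,stress,vs_yield,0.86,S,***,Table 1
MDA,TJ2049,control,V3_vs_R5,0.9,S,***,Table 1
MDA,TJ2049,control,vs_yield,0.71,S,***,Table 1
MDA,TJ2049,stress,V3_vs_R5,0.91,S,***,Table 1
MDA,TJ2049,stress,vs_yield,0.48,W,***,Table 1
MDA,MUNASQA,control,V3_vs_R5,0.94,S,***,Table 1
MDA,MUNASQA,control,vs_yield,0.28,W,*,Table 1
MDA,MUNASQA,stress,V3_vs_R5,0.9,S,***,Table 1
MDA,MUNASQA,stress,vs_yield,0.7,S,***,Table 1
CHL,TJ2049,control,V3_vs_R5,0.96,S,***,Table 1
CHL,TJ2049,control,vs_yield,0.37,W,**,Table 1
CHL,TJ2049,stress,V3_vs_R5,0.92,S,***,Table 1
CHL,TJ2049,stress,vs_yield,0.13,,ns,Table 1
CHL,MUNASQA,control,V3_vs_R5,0.85,S,***,Table 1
CHL,MUNASQA,control,vs_yield,0.76,S,***,Table 1
CHL,MUNASQA,stress,V3_vs_R5,0.88,S,***,Table 1
CHL,MUNASQA,stress,vs_yield,0.13,,ns,Table 1
CAR,TJ2049,control,V3_vs_R5,0.86,S,***,Table 1
CAR,TJ2049,control,vs_yield,0.95,S,***,Table 1
CAR,TJ2049,stress,V3_vs_R5,0.92,S,***,Table 1
CAR,TJ2049,stress,vs_yield,0.87,S,***,Table 1
CAR,MUNASQA,control,V3_vs_R5,0.89,S,***,Table 1
CAR,MUNASQA,control,vs_yield,0.92,S,***,Table 1
CAR,MUNASQA,stress,V3_vs_R5,0.9,S,***,Table 1
CAR,MUNASQA,stress,vs_yield,0.97,S,***,Table 1
LAI,TJ2049,control,V3_vs_R5,0.94,S,***,Table 2
LAI,TJ2049,control,vs_yield,0.01,,ns,Table 2
LAI,TJ2049,stress,V3_vs_R5,0.96,S,***,Table 2
LAI,TJ2049,stress,vs_yield,0.69,S,***,Table 2
LAI,MUNASQA,control,V3_vs_R5,0.79,S,***,Table 2
LAI,MUNASQA,control,vs_yield,0.04,,ns,Table 2
LAI,MUNASQA,stress,V3_vs_R5,0.39,W,***,Table 2
LAI,MUNASQA,stress,vs_yield,0.42,W,***,Table 2
LAR,TJ2049,control,V3_vs_R5,0.44,W,***,Table 2
LAR,TJ2049,control,vs_yield,-0.03,,ns,Table 2
LAR,TJ2049,stress,V3_vs_R5,-0.04,,ns,Table 2
LAR,TJ2049,stress,vs_yield,-0.66,S,***,Table 2
LAR,MUNASQA,control,V3_vs_R5,0.36,W,***,Table 2
LAR,MUNASQA,control,vs_yield,-0.04,,ns,Table 2
LAR,MUNASQA,stress,V3_vs_R5,0.4,W,***,Table 2
LAR,MUNASQA,stress,vs_yield,-0.27,W,***,Table 2
NAR,TJ2049,control,V3_vs_R5,0.22,,ns,Table 2
NAR,TJ2049,control,vs_yield,-0.03,,ns,Table 2
NAR,TJ2049,stress,V3_vs_R5,-0.04,,ns,Table 2
NAR,TJ2049,stress,vs_yield,0.01,,ns,Table 2
NAR,MUNASQA,control,V3_vs_R5,0.1,,ns,Table 2
NAR,MUNASQA,control,vs_yield,-0.01,,ns,Table 2
NAR,MUNASQA,stress,V3_vs_R5,0.17,,ns,Table 2
NAR,MUNASQA,stress,vs_yield,-0.03,,ns,Table 2
RGR,TJ2049,control,V3_vs_R5,-0.08,,ns,Table 2
RGR,TJ2049,control,vs_yield,-0.11,,ns,Table 2
RGR,TJ2049,stress,V3_vs_R5,0.33,,***,Table 2
RGR,TJ2049,stress,vs_yield,-0.07,,ns,Table 2
RGR,MUNASQA,control,V3_vs_R5,-0.45,W,ns,Table 2
RGR,MUNASQA,control,vs_yield,-0.05,,ns,Table 2
RGR,MUNASQA,stress,V3_vs_R5,0.22,,ns,Table 2
RGR,MUNASQA,stress,vs_yield,-0.13,,ns,Table 2
CGR,TJ2049,control,V3_vs_R5,-0.46,W,***,Table 2
CGR,TJ2049,control,vs_yield,-0.13,,ns,Table 2
CGR,TJ2049,stress,V3_vs_R5,0.17,,ns,Table 2
CGR,TJ2049,stress,vs_yield,0.02,,ns,Table 2
CGR,MUNASQA,control,V3_vs_R5,-0.2,,ns,Table 2
CGR,MUNASQA,control,vs_yield,-0.05,,ns,Table 2
CGR,MUNASQA,stress,V3_vs_R5,0.33,,ns,Table 2
CGR,MUNASQA,stress,vs_yield,0.03,,ns,Table 2
RWC,TJ2049,control,V3_vs_R5,0.87,S,***,Table 4
RWC,TJ2049,stress,V3_vs_R5,0.96,S,***,Table 4
RWC,MUNASQA,control,V3_vs_R5,0.9,S,***,Table 4
RWC,MUNASQA,stress,V3_vs_R5,0.94,S,***,Table 4
WUE,TJ2049,control,V3_vs_R5,0.89,S,***,Table 4
WUE,TJ2049,control,vs_yield,-0.44,W,**,Table 4
WUE,TJ2049,stress,V3_vs_R5,0.95,S,***,Table 4
WUE,TJ2049,stress,vs_yield,0.82,S,***,Table 4
WUE,MUNASQA,control,V3_vs_R5,0.91,S,***,Table 4
WUE,MUNASQA,control,vs_yield,-0.78,S,***,Table 4
WUE,MUNASQA,stress,V3_vs_R5,0.96,S,***,Table 4
WUE,MUNASQA,stress,vs_yield,0.84,S,***,Table 4
CTD,TJ2049,control,V3_vs_R5,0.93,S,***,Table 4
CTD,TJ2049,control,vs_yield,0.7,S,***,Table 4
CTD,TJ2049,stress,V3_vs_R5,0.91,S,***,Table 4
CTD,TJ2049,stress,vs_yield,-0.79,S,***,Table 4
CTD,MUNASQA,control,V3_vs_R5,0.95,S,***,Table 4
CTD,MUNASQA,control,vs_yield,0.76,S,***,Table 4
CTD,MUNASQA,stress,V3_vs_R5,0.97,S,***,Table 4
CTD,MUNASQA,stress,vs_yield,-0.85,S,***,Table 4
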