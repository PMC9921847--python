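parameter,mean,sd,low,high,units
HRmin,,,50,,bpm
HRmax,,,,120,bpm
MeanHR,,,50,120,bpm
MeanRR,,,,,ms
SDNN,141,39,102,180,ms
SDANN,127,35,92,162,ms
RMSSD,27,12,15,39,ms
NN50,,,,,count
pNN50,,,,,%
SDindex,,,,,ms
HRVti,37,15,22,52,
TINN,,,,,ms
TP,3466,1018,2448,4484,ms2
VLF,,,,,ms2
LF,1170,416,754,1586,ms2
HF,975,203,772,1178,ms2
LFnu,54,4,50,58,%
HFnu,29,3,26,32,%
LF/HF,,,1.5,2.0,
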