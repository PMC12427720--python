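gene,efficiency_percent,r_squared
ACT,104,0.998
TUA,101,0.996
TUB,102,0.999
GAPDH,101,0.999
EF-1γ,101,0.998
UBQ,100,0.999
UBC,101,0.998
60SrRNA,101,0.997
eIF6A,100,0.99
SKD1,102,0.994
YLS8,102,0.999
NDUFA13,104,0.999
PAL,104,0.997
CHS,105,0.999
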