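gene,gene_id,fold_change,p_value
VEGFA,397157,0.069689389,0.001912689
CYR61,100153791,0.080657036,0.0000754
AR,397582,0.1059863,0.000138367
EGR2,100038004,0.165503832,0.007949861
EDNRA,397457,0.166939028,0.00185422
NEBL,100522395,0.187213468,0.005937926
TGFBR3,397512,0.196522244,0.000405979
GJA1,100518636,0.206907347,0.000107676
FST,445002,0.224696558,0.000364693
CTNNA2,100525337,0.229925246,0.000512181
RTN4,100170118,0.23137773,0.027495815
SLITRK3,106504067,0.239141911,0.004260951
INHBA,397093,0.241259771,0.000148036
CDK6,100518921,0.248001413,0.006042481
LAMB2,101101688,0.278857947,0.000187911
ROBO2,100517681,0.283748864,0.001183495
IHH,397174,0.304995843,0.000551261
ZCCHC11,100516979,0.3216223,0.019809962
APP,397663,0.324138605,0.005602323
WWTR1,100522573,0.327202092,0.000254025
CD9,397067,0.329283105,0.006332387
SEMA5A,100737194,0.353391715,0.001092396
ITGB1,397019,0.366233017,0.003705215
SMAD4,397142,0.367802201,0.001238681
MAP3K1,396617,0.36876538,0.024748462
UBE2B,100513527,0.382779667,0.041104659
NOTCH2,100153369,0.3848262,0.002523723
RYK,100523513,0.421903006,0.00439989
SPTA1,100152068,0.427042121,0.002476662
KIT,396810,0.430444215,0.00255635
TPM1,100037999,0.433963109,0.001632742
CAPZA2,100037958,0.434375309,0.017755958
MMP14,397471,0.488721147,0.038060423
ARHGEF2,100145887,2.656199858,0.006431804
FN1,397620,2.679580656,0.001210303
MAP1B,100519062,2.788554105,0.00105385
SOX9,396840,3.503340174,0.000620008
CXCL12,494460,3.934705791,0.003163632
DAB2,100519746,4.008208178,0.001912689
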