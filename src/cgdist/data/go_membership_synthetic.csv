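term,gene
cellular component morphogenesis,ARHGEF2
cellular component morphogenesis,MAP1B
cellular component morphogenesis,CXCL12
cellular component morphogenesis,FN1
cellular component morphogenesis,DAB2
cellular component morphogenesis,SOX9
cellular component morphogenesis,GJA1
cellular component morphogenesis,CTNNA2
cellular component morphogenesis,RTN4
cellular component morphogenesis,APP
cellular component morphogenesis,SPTA1
cellular component morphogenesis,TPM1
cellular component morphogenesis,CAPZA2
cellular component morphogenesis,ITGB1
cellular component morphogenesis,NEBL
negative regulation of cell differentiation,SOX9
negative regulation of cell differentiation,NOTCH2
negative regulation of cell differentiation,FST
negative regulation of cell differentiation,INHBA
negative regulation of cell differentiation,IHH
negative regulation of cell differentiation,WWTR1
negative regulation of cell differentiation,CDK6
negative regulation of cell differentiation,SMAD4
negative regulation of cell differentiation,AR
negative regulation of cell differentiation,EGR2
negative regulation of cell differentiation,KIT
negative regulation of cell differentiation,TGFBR3
morphogenesis of a branching structure,MMP14
morphogenesis of a branching structure,VEGFA
morphogenesis of a branching structure,EDNRA
morphogenesis of a branching structure,ROBO2
morphogenesis of a branching structure,SEMA5A
morphogenesis of a branching structure,IHH
morphogenesis of a branching structure,FN1
morphogenesis of a branching structure,MAP3K1
morphogenesis of a branching structure,CXCL12
branching morphogenesis of a tube,MMP14
branching morphogenesis of a tube,VEGFA
branching morphogenesis of a tube,EDNRA
branching morphogenesis of a tube,IHH
branching morphogenesis of a tube,CYR61
branching morphogenesis of a tube,RYK
branching morphogenesis of a tube,NOTCH2
regulation of cellular component size,CAPZA2
regulation of cellular component size,SPTA1
regulation of cellular component size,TPM1
regulation of cellular component size,APP
regulation of cellular component size,CD9
regulation of cellular component size,LAMB2
regulation of cellular component size,UBE2B
regulation of cellular component size,ZCCHC11
regulation of cellular component size,SLITRK3
regulation of cellular component size,CTNNA2
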