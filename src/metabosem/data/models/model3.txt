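# Model 3: family history predicts obesity; obesity drives the metabolite
# cascade of hypothesis 1 (no direct family-history -> metabolite paths).
FHOB =~ MomFHOB + DadFHOB + IndFHOB
Obesity =~ BMI + Abd_circumf + FAT
AA1 =~ Arginine + Glycine + Leucine + Phenylalanine + Valine
AA2 =~ Citruline + Alanine + Methionine + Tyrosine + Ornitine + Proline
AC1 =~ C2 + C3 + C4
AC2 =~ C5 + C6 + C8 + C10 + C10:1 + C10:2 + C12 + C12:1 + C14 + C14:1 + C14:2
AC3 =~ C0 + C16 + C16:1 + C18:2
AC4 =~ C18:1OH + C18OH
INFL =~ TNFa + IL6
NAFLD =~ USG + ALT + AST
Obesity ~ FHOB
AA1 ~ Obesity
AA2 ~ Obesity
AC1 ~ AA2
AC2 ~ AA1 + AA2
AC3 ~ AA1
AC4 ~ AA1 + AA2
INFL ~ AC1 + AC3 + AC4 + AA1 + AA2
NAFLD ~ AC2 + AC3 + AC4
Matsuda ~ AC3 + AC4 + AA2
CRP ~ Obesity + NAFLD
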