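name,formula,category
Tridecane,C13H28,FA
"Heneicosanedioic acid, MG derivatives",C21H40O4,FA
TG derivatives (C69),C69H120O6,GL
DG derivatives (C43),C43H64O5,GL
MG derivatives (C25),C25H48O4,GL
DG derivatives (C37),C37H70O5,GL
DG derivatives (C39),C39H68O5,GL
TG derivatives (C59),C59H94O6,GL
PA derivatives,C39H69O8P,GP
"PC derivatives, PE derivatives",C42H72NO8P,GP
PG(17:0/20:4(5Z 8Z 11Z 14Z)),C43H81NO10P,GP
Tetrahydropteroyltri-L-glutamate,C24H34N8O12,FA
Behenyl alcohol,C22H46O,FA
"Pentamethyleicosapentaen-1-ol; 15-methyl-1,2-heneicosanediol",C25H42O,FA
Oxodocosanoic acid derivatives,C22H42O3,FA
AMC arachidonoyl amide,C30H39NO3,FA
"Docosapentaenoyl carnitine, clupanodonyl carnitine",C29H47NO4,FA
PC derivatives (C39),C39H79NO8P,GP
PC derivatives (C24),C24H50NO7P,GP
Sericetin diacetate,C29H28O7,PK
Dodecaprenyl diphosphate,C60H100O7P2,PR
Steroid derivative (Finasteride-like),C23H36N2O2,ST
Steroid derivatives (C21),C21H32N2O2,ST
Steroid derivative (o-Hydroxyfinasteride-like),C23H36N2O3,ST
Vitamin D3 derivatives (C29H50O2),C29H50O2,ST
Vitamin D3 derivative (C27H38O2),C27H38O2,ST
Vitamin D3 derivative (C29H50O4),C29H50O4,ST
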