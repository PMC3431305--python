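ion_id,rt,mz,adduct,adduct_mass,dppm,identity,formula,category,overexpressed_in,broad_class
0.49_104.1077,0.49,104.1077,[M+H+Na]2+,184.2191,0,Tridecane,C13H28,FA,BW,NP
7.43_339.2898,7.43,339.2898,[M+H-H2O]+,356.2926,0,"Heneicosanedioic acid, 6 MG derivatives",C21H40O4,FA,BW,NP
6.14_349.3104,6.14,349.3104,[M+3H]3+,1044.9085,0,7 TG derivatives,C69H120O6,GL,BW,PL
2.34_353.2280,2.34,353.2280,[M+2Na]2+,660.4754,3,3 DG derivatives,C43H64O5,GL,BW,PL
6.58_377.3415,6.58,377.3415,[M+H-2H2O]+,412.3553,2,2 MG derivatives,C25H48O4,GL,BW,PL
7.41_595.5318,7.41,595.5318,[M+H]+,594.5223,3,12 DG derivatives,C37H70O5,GL,BW,PL
7.07_617.5147,7.07,617.5147,[M+H]+,616.5067,1,21 DG derivatives,C39H68O5,GL,BW,PL
7.42_937.6763,7.42,937.6763,[M+K]+,898.7050,8,8 TG derivatives,C59H94O6,GL,BW,PL
8.50_719.4624,8.50,719.4624,[M+Na]+,696.4730,0,2 PA derivatives,C39H69O8P,GP,BW,PL
8.50_741.4486,8.50,741.4486,[M+2Na-H]+,696.4730,6,2 PA derivatives,C39H69O8P,GP,BW,PL
7.07_782.5360,7.07,782.5360,[M+CH3OH+H]+,749.4996,3,"3 PC derivatives, 2 PE derivatives",C42H72NO8P,GP,BW,PL
7.42_803.5648,7.42,803.5648,[M+H]+,802.5598,2,PG(17:0/20:4(5Z 8Z 11Z 14Z)),C43H81NO10P,GP,BW,PL
7.40_936.6635,7.40,936.6635,,,,,,NC,BW,NC
7.40_941.6199,7.40,941.6199,,,,,,NC,BW,NC
7.08_958.6475,7.08,958.6475,,,,,,NC,BW,NC
7.09_963.6014,7.09,963.6014,,,,,,NC,BW,NC
1.67_325.1129,1.67,325.1129,[M+H+Na]2+,626.2296,0,Tetrahydropteroyltri-L-glutamate,C24H34N8O12,FA,DW,NP
2.25_365.3160,2.25,365.3160,[M+K]+,326.3549,5,Behenyl alcohol,C22H46O,FA,DW,NP
2.38_381.3093,2.38,381.3093,[M+Na]+,358.3236,9,"Pentamethyleicosapentaen-1-ol; 15-methyl-1,2-heneicosanediol",C25H42O,FA,DW,NP
2.46_381.3096,2.46,381.3096,[M+Na]+,358.3236,8,"Pentamethyleicosapentaen-1-ol; 15-methyl-1,2-heneicosanediol",C25H42O,FA,DW,NP
2.08_393.2754,2.08,393.2754,[M+K]+,354.3134,2,4 oxodocosanoic acid derivatives,C22H42O3,FA,DW,NP
3.75_494.3259,3.75,494.3259,[M+CH3OH+H]+,461.2930,1,AMC arachidonoyl amide,C30H39NO3,FA,DW,NP
3.59_518.3227,3.59,518.3227,[M+2Na-H]+,473.3505,1,"Docosapentaenoyl carnitine, clupanodonyl carnitine",C29H47NO4,FA,DW,NP
2.23_361.2844,2.23,361.2844,[M+2H]2+,720.5543,0,7 PC derivatives,C39H79NO8P,GP,DW,PL
3.59_518.3227,3.59,518.3227,[M+Na]+,495.3325,1,5 PC derivatives,C24H50NO7P,GP,DW,PL
2.46_363.3007,2.46,363.3007,,,,,,NC,DW,NC
1.66_533.1525,1.66,533.1525,[M+2Na-H]+,488.1835,4,Sericetin diacetate,C29H28O7,PK,DW,PL
3.94_1039.6640,3.94,1039.6640,[M+2Na-H]+,994.6944,1,Dodecaprenyl diphosphate,C60H100O7P2,PR,DW,PL
5.21_337.2678,5.21,337.2678,[M+H-2H2O]+,372.2777,8,Steroid derivative (Finasteride-like),C23H36N2O2,ST,DW,NP
2.20_377.2804,2.20,377.2804,[M+CH3OH+H]+,344.2464,1,6 steroid derivatives,C21H32N2O2,ST,DW,NP
2.30_379.2931,2.30,379.2931,[M+Li]+,372.2777,1,Steroid derivative (Finasteride-like),C23H36N2O2,ST,DW,NP
2.24_379.2940,2.24,379.2940,[M+Li]+,372.2777,0,Steroid derivative (Finasteride-like),C23H36N2O2,ST,DW,NP
2.22_395.2897,2.22,395.2897,[M+Li]+,388.2726,2,Steroid derivative (o-Hydroxyfinasteride-like),C23H36N2O3,ST,DW,NP
6.96_413.3784,6.96,413.3784,[M+H-H2O]+,430.3811,0,8 Vitamin D3 derivatives,C29H50O2,ST,DW,NP
2.21_417.2756,2.21,417.2756,[M+Na]+,394.2872,1,Vitamin D3 derivative,C27H38O2,ST,DW,NP
6.28_427.3589,6.28,427.3589,[M+H-2H2O]+,462.3709,1,Vitamin D3 derivative,C29H50O4,ST,DW,NP
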