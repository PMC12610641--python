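compound,formula,class,rt,F023,F054,F055
"(E,E)-1,3,5-Heptatriene",C7H10,aliphatic_alkene,8.184,ND,0.36 ± 0.14,ND
1-Hexanol,C6H14O,aliphatic_alcohol,11.5,ND,0.16 ± 0.08,ND
α-Thujene,C10H16,monoterpene_hydrocarbon,14.207,0.11 ± 0.01,ND,0.26 ± 0.04
α-Pinene,C10H16,monoterpene_hydrocarbon,14.626,4.55 ± 0.65,9.24 ± 1.27,2.52 ± 0.50
Sabinene,C10H16,monoterpene_hydrocarbon,16.503,0.55 ± 0.08,0.13 ± 0.02,ND
β-Pinene,C10H16,monoterpene_hydrocarbon,17.009,8.05 ± 1.21,3.50 ± 0.57,10.32 ± 4.32
β-Myrcene,C10H16,monoterpene_hydrocarbon,17.364,3.79 ± 0.47,4.17 ± 0.45,3.98 ± 0.32
Butyl butanoate,C8H16O2,aliphatic_ester,17.539,ND,0.36 ± 0.10,ND
α-Terpinene,C10H16,monoterpene_hydrocarbon,18.730,0.08 ± 0.01,ND,0.15 ± 0.01
P-Cymene,C10H14,monoterpene_hydrocarbon,19.122,0.07 ± 0.01,ND,0.06 ± 0.003
D-Limonene,C10H16,monoterpene_hydrocarbon,19.367,0.89 ± 0.10,0.93 ± 0.12,ND
β-Phellandrene,C10H16,monoterpene_hydrocarbon,19.575,ND,ND,1.54 ± 0.11
β-Ocimene,C10H16,monoterpene_hydrocarbon,20.151,0.31 ± 0.02,0.47 ± 0.02,0.37 ± 0.05
γ-Terpinene,C10H16,monoterpene_hydrocarbon,20.838,0.16 ± 0.03,0.06 ± 0.02,0.28 ± 0.01
Terpinolene,C10H16,monoterpene_hydrocarbon,22.389,0.17 ± 0.02,0.11 ± 0.01,0.33 ± 0.02
Linalool,C10H18O,oxygenated_monoterpene,23.068,ND,0.21 ± 0.04,ND
Nonanal,C9H18O,aliphatic_aldehyde,23.287,ND,0.13 ± 0.05,ND
Terpinen-4-ol,C10H18O,oxygenated_monoterpene,26.263,0.25 ± 0.06,0.14 ± 0.03,0.18 ± 0.02
Butyl caproate,C10H20O2,aliphatic_ester,26.440,ND,0.30 ± 0.08,ND
α-Terpineol,C10H18O,oxygenated_monoterpene,26.723,0.22 ± 0.04,0.12 ± 0.02,ND
Bicyclogermacrene,C15H24,sesquiterpene_hydrocarbon,30.701,0.04 ± 0.02,0.17 ± 0.02,0.19 ± 0.01
γ-Elemene,C15H24,sesquiterpene_hydrocarbon,31.309,0.35 ± 0.12,2.00 ± 0.20,1.72 ± 0.09
α-Cubebene,C15H24,sesquiterpene_hydrocarbon,31.780,0.50 ± 0.09,0.55 ± 0.03,1.05 ± 0.03
Ylangene,C15H24,sesquiterpene_hydrocarbon,32.630,ND,0.48 ± 0.02,ND
γ-Muurolene,C15H24,sesquiterpene_hydrocarbon,33.012,9.49 ± 0.42,9.55 ± 1.10,10.37 ± 0.26
β-Elemene,C15H24,sesquiterpene_hydrocarbon,33.413,3.60 ± 0.88,4.09 ± 0.45,9.73 ± 0.46
Isocaryophyllene,C15H24,sesquiterpene_hydrocarbon,33.975,0.79 ± 0.18,ND,ND
β-Caryophyllene,C15H24,sesquiterpene_hydrocarbon,34.864,34.02 ± 4.22,28.54 ± 1.81,12.80 ± 0.44
Aciphyllene,C15H24,sesquiterpene_hydrocarbon,35.067,2.72 ± 0.38,2.13 ± 0.24,ND
α-Santoline alcohol,C10H18O,oxygenated_monoterpene,35.319,0.80 ± 0.09,3.67 ± 2.02,0.90 ± 0.05
Humulene,C15H24,sesquiterpene_hydrocarbon,36.076,10.19 ± 1.24,5.67 ± 0.71,3.66 ± 0.11
Alloaromadendrene,C15H24,sesquiterpene_hydrocarbon,36.223,1.05 ± 0.04,ND,1.48 ± 0.10
γ-Maaliene,C15H24,sesquiterpene_hydrocarbon,36.720,2.30 ± 1.60,5.28 ± 0.63,12.50 ± 0.88
Germacrene D,C15H24,sesquiterpene_hydrocarbon,37.038,0.59 ± 0.07,ND,2.06 ± 0.11
α-Guaiene,C15H24,sesquiterpene_hydrocarbon,37.592,2.77 ± 0.70,6.81 ± 0.92,ND
β-Selinene,C15H24,sesquiterpene_hydrocarbon,37.728,ND,ND,10.87 ± 0.48
α-Selinene,C15H24,sesquiterpene_hydrocarbon,38.035,ND,ND,2.89 ± 0.19
γ-Cadinene,C15H24,sesquiterpene_hydrocarbon,38.277,1.31 ± 0,ND,1.52 ± 0.07
δ-Amorphene,C15H24,sesquiterpene_hydrocarbon,38.442,3.37 ± 0.44,6.30 ± 0.92,3.22 ± 0.46
γ-Amorphene,C15H24,sesquiterpene_hydrocarbon,38.995,0.25 ± 0.06,ND,0.42 ± 0.01
α-Cadinene,C15H24,sesquiterpene_hydrocarbon,39.150,0.17 ± 0.02,ND,0.36 ± 0.01
Elemol,C15H26O,oxygenated_sesquiterpene,39.594,0.26 ± 0.12,ND,0.74 ± 0.04
E-Nerolidol,C15H26O,oxygenated_sesquiterpene,39.900,1.37 ± 0.32,0.98 ± 0.20,ND
Caryophyllene oxide,C15H24O,oxygenated_sesquiterpene,41.228,0.91 ± 0.17,0.35 ± 0.03,0.16 ± 0.01
γ-Eudesmol,C15H26O,oxygenated_sesquiterpene,43.299,0.13 ± 0.03,ND,0.18 ± 0.02
t-Cadinol,C15H26O,oxygenated_sesquiterpene,43.769,0.29 ± 0.09,0.71 ± 0.10,0.33 ± 0.05
t-Muurolol,C15H26O,oxygenated_sesquiterpene,44.348,1.11 ± 0.06,0.41 ± 0.08,ND
β-Selinenol,C15H26O,oxygenated_sesquiterpene,44.505,ND,ND,0.92 ± 0.10
γ-Dodecalactone,C12H22O2,lactone,45.087,ND,0.24 ± 0.07,ND
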