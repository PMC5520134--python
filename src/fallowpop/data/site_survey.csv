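name,country,map_no,n,region,source,park,a,ar,fis,ho,he,hwe_p
spain_central,Spain,13,15,iberia,iberia,0,1.7,1.51,0.21,0.16,0.20,0.75
spain_southwest,Spain,12,25,iberia,iberia,0,2.3,1.75,0.13,0.20,0.23,0.83
spain_north,Spain,14,15,iberia,iberia,0,1.6,1.47,-0.21,0.21,0.18,0.91
spain_asturias,Spain,11,15,iberia,iberia,0,1.8,1.60,0.15,0.15,0.17,0.22
portugal_castelo_branco,Portugal,10,13,iberia,iberia,0,1.7,1.61,0.15,0.19,0.23,0.89
italy_grosetto,Italy,18,15,italia,italia,0,2.3,2.21,0.04,0.42,0.43,0.25
italy_siena,Italy,19,14,italia,italia,0,2.6,2.42,0.08,0.45,0.48,0.63
italy_san_rossore,Italy,20,14,italia,italia,0,2.2,2.05,0.11,0.37,0.41,0.19
england_essex,England,8,15,northern,italia,0,2,1.88,-0.03,0.34,0.33,0.29
england_oxfordshire,England,6,9,northern,italia,1,2.2,2.13,0.28,0.25,0.33,0.04
england_cambridge,England,7,15,northern,italia,0,2,1.90,-0.04,0.35,0.34,0.08
england_shropshire,England,4,9,northern,italia,1,2.2,1.76,-0.12,0.29,0.26,0.18
england_lincolnshire,England,5,15,northern,italia,1,2.1,1.90,0.01,0.30,0.31,0.18
england_norfolk,England,9,24,northern,italia,1,2.2,2.00,0.08,0.35,0.38,0.07
ireland_north_central,Ireland,1,13,northern,italia,0,2.1,1.97,0.19,0.25,0.31,0.64
ireland_wicklow,Ireland,3,13,northern,italia,0,1.8,1.62,0.29,0.16,0.22,0.08
ireland_south,Ireland,2,10,northern,italia,0,2,1.94,0.29,0.26,0.36,0.45
sweden_kristianstad,Sweden,15,15,northern,italia,0,2.1,1.97,-0.03,0.35,0.34,0.36
hungary_gyula,Hungary,17,7,northern,italia,0,2.2,2.10,-0.14,0.34,0.30,0.93
hungary_labod,Hungary,16,7,northern,italia,0,2.1,2.07,-0.06,0.39,0.37,0.52
canada_sidney_island,Canada,,24,northern,italia,0,1.6,1.46,-0.09,0.15,0.14,0.83
turkey_antalya,Turkey,23,24,anatolia,anatolia,1,1.7,1.53,-0.22,0.22,0.18,<0.01
turkey_rhodes,Turkey,24,24,anatolia,anatolia,0,2.7,2.12,0.23,0.26,0.34,0.01
bulgaria_rhodopes,Bulgaria,22,14,anatolia,anatolia,0,1.7,1.62,0.10,0.19,0.21,0.95
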