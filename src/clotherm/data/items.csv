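item_id,name,brand_model,size,mass_g,materials,it,fcl,iclu,body_region
1,Socks,"Groenendijk, Brandweer Nederland",43-45,62.2,,0.107,1.01,0.009,feet
2,Low safety shoes,"Neskrid, Crow S3 low","45, W11",1554.1,"PU sole, leather uppers, fabric padding",0.107,1.02,0.010,feet
3,High safety shoes,"Haix, Airpower XR1",45,2153.4,"PU sole, leather uppers, fabric padding",0.109,1.06,0.015,feet
4,Firefighter boots,"Haix, Fire flash gamma","44, W12",2939.3,"PU sole, leather uppers, fabric padding, Gore-Crosstech",0.113,1.07,0.021,feet
5,Baseball cap,"Groenendijk, Brandweer Nederland",one size,91.3,"50% cotton, 48% polyester, 2% elastane",0.103,1.01,0.005,head
6,Beanie,"Groenendijk, Brandweer Nederland",one size,49.5,"80% wool, 20% acrylic",0.104,1.00,0.005,head
7,Balaclava/fire hood,"Viking Life Saving Equipment A/S, Type 1",one size,119.4,100% aramid,0.107,1.01,0.009,head
8,Boxershorts (underwear),GS Sport,XL,69.4,"95% cotton, 5% elastane",0.106,1.01,0.008,underwear
9,T-shirt (underwear),"Narkonteks, Brandweer Nederland","L, regular",182.1,"60% mode acrylic, 40% cotton, Ribana, 190 g/m2",0.124,1.03,0.027,underwear
10,Belt (stretch-heavy),Groenendijk,105,106.2,,0.102,1.00,0.003,waist
11,"Polo shirt, short sleeves","Narkonteks, Brandweer Nederland","L, regular",345.8,"60% mode acrylic, 40% cotton, Pique, 200 g/m2",0.131,1.08,0.040,torso
12,"Polo shirt, long sleeves","Narkonteks, Brandweer Nederland","L, regular",427.2,"60% mode acrylic, 40% cotton, Pique, 200 g/m2",0.140,1.09,0.049,torso
13,(Polo)sweater (400 gr),"Narkonteks, Brandweer Nederland","L, regular",842.1,"50% mode acrylic, 50% cotton, three thread fleece, 400 g/m2",0.148,1.14,0.061,torso
14,Softshell (zip open at neck),"SIOEN, Brandweer Nederland","L, regular",787.2,,0.145,1.11,0.056,torso
14A,Softshell (fully zipped),"SIOEN, Brandweer Nederland","L, regular",787.2,,0.146,1.14,0.059,torso
15,Working trousers,"SIOEN, Brandweer Nederland","52, regular",697.7,"42% modacrylic, 29% cotton, 19% polyamide FR, 5% aramid, 4% elastolefin, 1% antistatic (AST) yarn",0.136,1.12,0.047,legs
16,Safety gloves (cut resistant) for technical rescue,"GUIDE, 313",11,82.7,,0.102,1.01,0.004,hands
17,Safety gloves (for structural firefighting),"Eska, Helios E",10,366.2,,0.102,1.03,0.005,hands
18,Technical rescue jacket,"SIOEN, 233 Proviz/AS","L, regular",1431.7,"OL: 54% Nomex, 28% polyester, 17% viscose FR, 1% AST; lining: 100% aramid laminated with bi-component ePTFE membrane + AST",0.162,1.17,0.077,torso
19,Firefighter top layer jacket (to be used on top of item 18),"SIOEN, TL TWIN/AS","L, regular",1312.0,"OL: 100% aramid + AST; lining: 50% aramid, 50% viscose FR",0.171,1.17,0.087,torso
21,Firefighter jacket (corresponds to EN 469),"SIOEN, 830 Twin/AS","L, regular",1793.8,"OL: 100% aramid + AST; ML: 100% aramid laminated with bi-component ePTFE membrane; lining: 100% aramid + AST",0.177,1.23,0.097,torso
22,"Firefighter trousers, standard model (corresponds to EN 469)",SIOEN,"L, regular",1712.5,"OL: 100% aramid + AST; ML: 100% aramid laminated with bi-component ePTFE membrane; lining: 100% aramid + AST",0.168,1.32,0.093,legs
23,"Firefighter trousers, dungarees (corresponds to EN 469)",SIOEN,"L, regular",1795.3,"OL: 100% aramid + AST; ML: 100% aramid laminated with bi-component ePTFE membrane; lining: 100% aramid + AST",0.167,1.36,0.095,legs
24,Firefighter coverall (corresponds to EN 469),SIOEN,"L, regular",2883.2,"OL: 100% aramid + AST; ML: 100% aramid laminated with bi-component ePTFE membrane; lining: 100% aramid + AST",0.303,1.47,0.236,full_body
25,Firefighter helmet,"Draeger, HPS 7000 H1",50-60,1621.3,,0.103,1.07,0.011,head
26,"Face and neck cover (hollanddoek, connected to helmet, closed in front)",Draeger,one size,161.3,,0.107,1.12,0.018,head
26A,"Face and neck cover (hollanddoek, connected to helmet, open in front, fixed at back side)",Draeger,one size,161.3,,0.105,1.10,0.016,head
27,Technical rescue helmet,"MSA Gallet, F2 X-trem",52-64 cm,830.1,,0.102,1.05,0.008,head
28,"Self-Contained Breathing Apparatus (SCBA, bottles only)","Interspiro, V-RWS",XXL,11469.9,Composite with 2 bottles,0.104,1.15,0.018,ppe
29,High visibility vest,"Coprit, V-RWS",XXL,166.4,100% polyester,0.117,1.08,0.026,torso
30,Winter jacket (doorwerkjas) with thermal lining,"SIOEN, Brandweer Nederland","L, regular",1594.3,"OL and lining: 100% polyester; membrane: 100% polyurethane; thermal liner: 100% polyester insulation between 100% polyamide layers",0.163,1.19,0.080,torso
30A,Winter jacket (doorwerkjas) without thermal lining (outer shell only),"SIOEN, Brandweer Nederland","L, regular",1253.1,"OL and lining: 100% polyester; membrane: 100% polyurethane",0.151,1.16,0.066,torso
30B,Winter jacket (doorwerkjas) outer shell only with hood half way,"SIOEN, Brandweer Nederland","L, regular",1353.0,"OL and lining: 100% polyester; membrane: 100% polyurethane",0.161,1.19,0.078,torso
30C,Thermal liner of the winter jacket alone,"SIOEN, Brandweer Nederland","L, regular",341.2,100% polyester insulation between 100% polyamide layers,0.156,1.13,0.068,torso
31,"SCBA system (items 26, 28 and facemask from Draeger fitting the helmet)","Draeger, FPS 7000/Interspiro","M, HMC",755.0,Rubber/plastic glass,0.113,1.26,0.034,ppe
31A,Face mask,Interspiro,,1228.7,Rubber/plastic glass,0.100,1.07,0.008,ppe
31B,SCBA system (items 28 and 31A),Interspiro,,12698.6,"Rubber/plastic glass, composite",0.106,1.22,0.025,ppe
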