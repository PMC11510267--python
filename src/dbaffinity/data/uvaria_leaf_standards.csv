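id,name,neutral_formula,ion_formula,charge,rt_min,observed_mz,theoretical_mz,delta_ppm_printed,fragments,diagnostic,content_mg_per_g,bioactivity
1,liquiritigenin,C15H12O4,C15H11O4,-1,10.56,255.0661,255.0663,0.7843,255.0659;119.0492;91.0178,119.0492;91.0178,0.577,anti-inflammatory
2,isoliquiritigenin,C15H12O4,C15H11O4,-1,11.50,255.0661,255.0663,0.7843,255.0661;119.0492;91.0178;135.0441,135.0441;119.0492,0.012,antitumor
3,pinocembrin,C15H12O4,C15H11O4,-1,12.20,255.0662,255.0663,0.3921,255.0661;213.0552;151.0029,213.0552;151.0029,0.072,antitumor
4,oroxylin A,C16H12O5,C16H11O5,-1,12.29,283.0612,283.0612,0,283.0611;268.0377,268.0377,0.048,antioxidant
5,wogonin,C16H12O5,C16H11O5,-1,12.35,283.0611,283.0612,0.3533,283.0611;163.0027;268.0374;109.9998,163.0027;109.9998,0.026,anti-inflammatory
6,galangin 3-methyl ether,C16H12O5,C16H11O5,-1,12.52,283.0612,283.0612,0,239.0346;211.0395;167.0494,239.0346;211.0395;167.0494,0.012,antibiotic
7,isoquercitrin,C21H20O12,C21H19O12,-1,9.54,463.0873,463.0882,1.9438,463.0874;300.0273;271.0247;255.0298,,0.017,anti-inflammatory
8,hyperoside,C21H20O12,C21H19O12,-1,9.43,463.0875,463.0882,1.5118,463.0874;300.0273;271.0247,,0.025,anti-inflammatory
9,quercetin 3-O-β-D-glucuronide,C21H18O13,C21H17O13,-1,9.57,477.0674,477.0675,0.2096,301.0353;151.0028;109.0284,,0.138,antimicrobial
10,phloridzin,C21H24O10,C21H23O10,-1,9.93,435.1280,435.1297,3.9080,273.0770;167.0341;123.0442;119.0492,,0.034,antioxidant
11,tiliroside,C30H26O13,C30H25O13,-1,10.96,593.1298,593.1301,0.5059,285.0397;255.0292;227.0341,,0.542,antioxidant
12,kaempferol,C15H10O6,C15H9O6,-1,11.36,285.0405,285.0405,0,285.0405;117.0335;93.0334,,0.033,anti-inflammatory
13,7-hydroxyflavone,C15H10O3,C15H9O3,-1,11.93,237.0553,237.0557,1.6877,237.0553;208.0524;91.0178,,0.027,antibacterial
14,chrysin,C15H10O4,C15H9O4,-1,12.51,253.0504,253.0506,0.7905,251.0500;209.0598;143.0491,,0.267,antitumor
15,galangin,C15H10O5,C15H9O5,-1,12.67,269.0456,269.0455,0.3717,269.0456;169.0650,,0.247,anti-inflammatory
16,myricetin,C15H10O8,C15H9O8,-1,9.86,317.0301,317.0303,0.6309,317.0301;151.0028;137.0234;109.0284,,0.036,antioxidant
17,D-fructose,C6H12O6,C6H13O6,1,13.82,181.0715,181.0707,4.4198,163.0385;149.0229;65.0393,,0.247,antioxidant
18,"1,2,3,4,6-penta-O-galloyl-β-D-glucopyranose",C41H32O26,C41H31O26,-1,9.46,939.1146,939.1109,3.9403,169.0134;125.0234;107.0127;95.0126,,0.547,antioxidant
19,sucrose,C12H22O11,C12H21O11,-1,0.53,341.1086,341.1089,0.8797,341.1086;179.0553;161.0448;89.0233,,0.986,sweetening agent
20,quinic acid,C7H12O6,C7H11O6,-1,0.55,191.0555,191.0561,3.1413,191.0555;93.0335;85.0283,,0.377,antioxidant
21,salicylic acid,C7H6O3,C7H5O3,-1,8.18,137.0234,137.0244,7.2992,137.0234;93.0333,,0.056,anti-inflammatory
22,methyl gallate,C8H8O5,C8H7O5,-1,3.06,183.0291,183.0299,4.3715,183.0291;124.0156;78.0099,,0.007,anti-inflammatory
23,protocatechuic acid,C7H6O4,C7H5O4,-1,1.6,153.0186,153.0193,4.5751,153.0186;109.0285;108.0206,,0.026,antimicrobial
24,"2,5-dihydroxybenzoic acid",C7H6O4,C7H5O4,-1,2,153.0186,153.0193,4.5751,153.0182;109.0284;108.0206,,0.015,improvements in vascular function
25,4-hydroxybenzaldehyde,C7H6O2,C7H5O2,-1,3.22,121.0285,121.0295,8.2644,121.0285;92.0257,,0.006,improvements in vascular function
26,caffeic acid,C9H8O4,C9H7O4,-1,4.6,179.0339,179.0350,6.1452,179.0345;136.0474;135.0441;133.0282,,0.012,antibacterial
27,cis-4-hydroxycinnamic acid,C9H8O3,C9H7O3,-1,7.11,163.0392,163.0401,5.5214,119.0492,,0.094,anti-SARS
28,ferulic acid,C10H10O4,C10H9O4,-1,8.71,193.0496,193.0506,5.1813,193.0136;178.0262;134.0364,,0.258,antibacterial
29,gallic acid,C7H6O5,C7H5O5,-1,0.86,169.0133,169.0142,5.3254,169.0133;125.0234,,4.800,antioxidant
30,ellagic acid,C14H6O8,C14H5O8,-1,9.5,300.9989,300.9990,0.3333,300.9990;145.0286;117.0335,,0.485,antioxidant
31,citric acid,C6H8O7,C6H7O7,-1,0.52,191.0189,191.0197,4.1884,111.0078;87.0076;85.0248,,0.757,improvements in vascular function
32,gallocatechin gallate,C22H18O11,C22H17O11,-1,7.98,457.0736,457.0776,8.7527,169.0133;125.0234,,0.274,antiviral
33,epicatechin gallate,C22H18O10,C22H17O10,-1,8.68,441.0831,441.0827,0.9070,289.0715;169.0134;125.0234;109.0285,,0.020,antioxidant
34,cholesteryl acetate,C29H48O2,C29H49O2,1,16.03,429.3706,429.3727,4.8951,429.3706;165.0912;91.0545;81.0705,,14.418,antitumor
35,(+)-4-cholesten-3-one,C27H44O,C27H45O,1,16.67,385.3459,385.3465,1.5584,385.3454;109.0649;97.0650;91.0545,,0.003,antitumor
36,betulin,C30H50O2,C30H51O2,1,15.38,443.3878,443.3884,1.3544,443.3497;105.0700;91.0547;81.0705,,0.130,antitumor
37,oleanolic acid,C30H48O3,C30H47O3,-1,15.18,455.3531,455.3531,0,455.3531,,0.026,antitumor
38,ethyl stearate,C20H40O2,C20H39O2,-1,16.22,311.2956,311.2956,0,311.1682;183.0114;119.0492,,0.209,antioxidant
39,oleic acid,C18H34O2,C18H33O2,-1,15.62,281.2487,281.2486,0.3558,281.2487,,0.046,antioxidant
40,stearic acid,C18H36O2,C18H35O2,-1,15.8,283.2643,283.2643,0,283.2643;92.1626,,0.197,antioxidant
41,L-(-)-proline,C5H9NO2,C5H10NO2,1,0.54,116.0708,116.0706,1.7241,116.0706;70.0657,,0.940,immune modulation
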