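case_id,alteration_category,gene_fc,mir_fc
E1450,Allelic Imbalance,3.67,1.77
E1535,Allelic Imbalance,0.87,1.41
E1566,Allelic Imbalance,25.25,26.53
E1860,Allelic Imbalance,0.36,2.07
E1866,Allelic Imbalance,,1
E1885,Allelic Imbalance,41.10,72.57
E0362,"Allelic Imbalance, CN Gain",0.98,12.02
E0844,"Allelic Imbalance, CN Gain",48.01,15.25
E1293,"Allelic Imbalance, CN Gain",3.26,0.81
E1546,"Allelic Imbalance, CN Gain",0.25,2.51
E1635,"Allelic Imbalance, CN Gain",1.52,0.56
E1862,"Allelic Imbalance, CN Gain",0.24,6.02
E1874,"Allelic Imbalance, CN Gain",0.38,1.61
E0796,"Allelic Imbalance, CN Gain, CN Loss",0.20,3.08
E1507,"Allelic Imbalance, CN Gain, CN Loss",0.7,8.61
E1575,"Allelic Imbalance, CN Gain, CN Loss",0.77,0.44
E0410,"Allelic Imbalance, CN Gain, LOH",1.05,10.65
E0387,"Allelic Imbalance, CN Loss",2.77,4.36
E1210,"Allelic Imbalance, CN Loss",0.15,5.58
E1242,"Allelic Imbalance, CN Loss",5.18,2.85
E1256,"Allelic Imbalance, CN Loss",10.25,1.11
E1520,"Allelic Imbalance, CN Loss",2.08,1.4
E1521,"Allelic Imbalance, CN Loss",5.03,1.07
E1532,"Allelic Imbalance, CN Loss",0.27,3.15
E1558,"Allelic Imbalance, CN Loss",18.69,7.58
E1572,"Allelic Imbalance, CN Loss",9.38,3.75
E1756,"Allelic Imbalance, CN Loss",0.25,8.6
E1782,"Allelic Imbalance, CN Loss",1.63,9.28
E1793,"Allelic Imbalance, CN Loss",,3.34
E1879,"Allelic Imbalance, CN Loss",59.56,1.65
E1897,"Allelic Imbalance, CN Loss",0.42,1.83
E1910,"Allelic Imbalance, CN Loss",1.04,1.27
E1542,CN Gain,186.84,13.01
E1584,CN Gain,7.37,9.93
E1416,CN Loss,7.70,2.7
E1510,CN Loss,0.53,7.83
E1610,CN Loss,1.11,38.59
E1475,"CN Loss, LOH",6.42,8.00
E1864,LOH,0.52,1.47
E0381,not observed,1.57,3.81
E0742,not observed,1.65,2.35
E0746,not observed,3.22,1.89
E0822,not observed,0.45,3.00
E1179,not observed,47.84,25.37
E1195,not observed,4.81,1.55
E1400,not observed,1.11,7.37
E1415,not observed,1.25,2.8
E1435,not observed,0.25,2.09
E1451,not observed,8.54,0.76
E1573,not observed,0.31,0.9
E1589,not observed,1.62,7.6
E1796,not observed,0.29,1.65
E1877,not observed,0.72,0.71
E1880,not observed,5.28,6.5
E1882,not observed,28.97,60.39
E1905,not observed,2.36,2.19
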