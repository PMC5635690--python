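# Published calculated/observed MS/MS fragment values per product, as printed
# (including occasional five-decimal entries in the source).
molecule	calc_mz	obs_mz
M1	137.0239	137.0231
M1	194.0817	194.0809
M1Tc	137.0239	137.0230
M1Tc	194.0817	194.0811
M1Tc	277.1175	277.1188
M1Tc	294.1443	294.1457
M2	72.0813	72.0813
M2	129.1392	129.1388
M2	194.0817	194.0810
M2	265.1552	265.1542
M2Tc	194.0817	194.0812
M2Tc	265.1552	265.1540
M2Tc	308.1610	308.1595
M2Tc	365.2178	365.2173
M2So	137.0239	137.0237
M2So	209.0926	209.0924
M2So	224.0559	224.0555
M2To	137.0239	137.0232
M2To	194.0817	194.0809
M2To	210.0766	210.0758
M2To	265.1552	265.1542
M2To	282.1807	282.1809
M2To	383.2283	383.2294
M4	86.0970	86.0970
M4	103.1229	103.1235
M4	137.0239	137.0232
M4	222.1130	222.1132
M5	72.0813	72.0815
M5	89.1068	89.1080
M5	137.0239	137.0234
M5	208.0974	208.0968
M5Tc	137.0239	137.0229
M5Tc	192.0661	192.0661
M5Tc	208.0974	208.0964
M5Tc	225.1228	225.1237
M5Tc	308.1599	308.1617
M5To	137.0239	137.0230
M5To	208.0974	208.0964
M5To	225.1228	225.1237
M5To	238.0715	238.0717
M5To	210.0766	210.0755
M6	137.0239	137.0232
M6	194.0817	194.0810
M6	251.1396	251.1381
M6	443.1925	443.1907
M6Tc	137.0239	137.0232
M6Tc	194.0817	194.0810
M6Tc	277.1188	277.1188
M6Tc	351.2021	351.2016
M6Tc	443.1925	443.1907
M6To	137.0239	137.0232
M6To	194.0817	194.0810
M6To	210.0766	210.0758
M6To	369.2127	369.2130
M7	120.0813	120.0811
M7	137.0239	137.0232
M7	256.0974	256.0964
M9	91.0548	91.0545
M9	180.0661	180.0651
M9Tc	91.0548	91.0546
M9Tc	180.0661	180.0652
M9Tc	287.1385	287.1381
M9Sc	91.0548	91.0548
M9Sc	287.1385	287.1385
M9To	91.0548	91.0548
M9To	345.1439	345.1460
M9To	389.1934	389.1956
M10	106.0657	106.0656
M10	137.0239	137.0237
M10	154.0493	154.0497
M11	120.0813	120.0813
M11	137.0239	137.0234
M11	256.0974	256.0963
M12	108.0449	108.0446
M12	137.0239	137.0232
M12	201.1017	201.1024
M21	128.1439	128.1435
M21	137.0239	137.0231
M21	145.1694	145.1699
M21	264.1600	264.1595
Ent	137.0239	137.02134
Ent	206.0459	206.0452
Ent	224.0553	224.0554
Ent	447.1034	447.1029
Ent trimer	137.0239	137.0230
Ent trimer	224.0559	224.0555
Ent trimer	447.1040	447.1018
Ent dimer	137.02139	137.0231
Ent dimer	196.0610	196.0609
Ent dimer	224.0559	224.0557
Ent monomer	106.0493	106.0503
Ent monomer	137.0239	137.0234
Thr-Ent dimer	137.0239	137.02131
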