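# Printed calculated fragment values with no depth-1 cleavage/neutral-loss
# explanation under the plain formula-sum convention (frozen; the test
# suite fails if an entry silently gains or loses an explanation).
molecule	calc_mz	nearest_predicted_mz
M1Tc	277.1175	277.1188
M1Tc	294.1443	294.1454
M2Tc	308.1610	306.1454
M2Tc	365.2178	365.2189
M2To	282.1807	282.1818
M2To	383.2283	383.2294
M5	89.1068	89.1079
M5Tc	225.1228	225.1239
M5Tc	308.1599	308.1610
M5To	225.1228	225.1239
M6	443.1925	268.1661
M6Tc	351.2021	351.2032
M6Tc	443.1925	469.2087
M6To	369.2127	369.2138
M9	91.0548	109.0290
M9	180.0661	151.1235
M9Tc	91.0548	109.0290
M9Tc	180.0661	192.0661
M9Tc	287.1385	287.1396
M9Sc	91.0548	109.0290
M9Sc	287.1385	287.1396
M9To	91.0548	109.0290
M9To	345.1439	370.1767
M9To	389.1934	388.1872
M10	154.0493	137.0239
M12	108.0449	109.0290
M12	201.1017	201.1028
M21	145.1694	145.1705
Ent dimer	137.02139	137.0239
Ent monomer	106.0493	106.0504
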