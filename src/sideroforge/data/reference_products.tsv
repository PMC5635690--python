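# Published calculated/observed [M+H]+ values for the characterized product set.
molecule	precursor_id	calc_mz	obs_mz
M1	1	211.1077	211.1073
M1Tc	1	430.1609	430.1601
M2	2	282.1812	282.1810
M2Tc	2	501.2344	501.2342
M2So	2	505.2293	505.2316
M2To	2	519.2449	519.2439
M4	4	239.1390	239.1389
M5	5	225.1234	225.1229
M5Tc	5	444.1765	444.1764
M5To	5	462.1871	462.1861
M6	6	268.1656	268.1654
M6Tc	6	487.2187	487.2187
M6To	6	505.2293	505.2290
M7	7	273.1234	273.1228
M9	9	287.1390	287.1389
M9Tc	9	506.1922	506.1923
M9Sc	9	492.1765	492.1754
M9To	9	524.2027	524.2033
M10	10	259.1077	259.1076
M11	11	273.1234	273.1230
M12	12	337.1183	337.1180
M21	21	281.1860	281.1857
Ent		670.1515	670.1509
Ent trimer		688.1621	688.1613
Ent dimer		465.1140	465.1133
Ent monomer		242.0659	242.0653
Thr-Ent dimer		493.1453	493.1448
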