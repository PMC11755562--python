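# Published physicochemical descriptor values for the 85-peptide EcoRI panel.
# mw (Da), pi, gravy come from the per-family peptide tables; aliphatic_index,
# hydrophilic_pct, aromatic_n, instability_index, net_charge_ph7 from the
# pooled descriptor table. Values are as printed, including the four staggered
# tail rows whose mw/pi/gravy cells are scrambled (see anomalies.tsv).
id	length	mw	pi	gravy	aliphatic_index	hydrophilic_pct	aromatic_n	instability_index	net_charge_ph7
BP1	14	1697.87	10.29	-2.529	27.86	79	1	118.93	3.09
BP2	12	1308.50	6.85	-0.183	121.67	42	1	46.85	0.09
BP3	14	1518.73	5.21	0.514	118.57	21	3	14.07	-0.91
BP4	14	1428.74	9.70	0.471	132.14	43	0	-10.29	2.00
BP5	13	1658.79	6.07	-1.508	37.69	54	3	29.55	0.00
BP6	14	1642.96	8.43	-0.800	118.57	57	0	18.61	1.00
BP7	12	1233.38	3.56	0.683	121.67	25	1	6.09	-2.00
BP8	12	1207.31	5.84	-0.350	56.67	50	1	15.86	0.00
BP9	14	1491.62	4.23	-0.929	69.29	43	1	-12.92	-2.00
BP10	14	1621.86	6.86	-0.243	104.29	36	2	-1.45	0.09
BP11	12	1325.57	8.75	0.117	162.50	42	0	36.47	1.00
BP12	13	1427.58	8.75	-1.254	82.31	54	0	27.46	1.00
BP13	12	1247.39	4.37	-0.050	90.00	42	0	85.61	-1.00
BP14	12	1390.58	6.47	-0.308	73.33	50	2	85.09	0.09
BP15	13	1580.80	4.51	0.500	112.31	31	4	45.70	-1.91
BP16	12	1323.42	3.80	-0.092	97.50	50	1	49.31	-2.00
BP17	12	1418.57	5.74	-0.942	80.83	42	1	18.93	0.00
BP18	13	1442.64	9.60	-0.285	127.69	46	0	11.72	1.00
BP19	12	1264.42	5.57	-0.067	81.67	33	1	38.71	0.00
BP20	13	1572.85	9.20	-0.854	82.31	54	2	39.13	2.04
BP21	14	1497.68	3.80	0.271	97.86	36	1	21.12	-1.00
BP22	14	1789.10	4.68	-0.186	55.71	43	3	20.00	-1.00
BP23	14	1658.93	4.37	0.714	104.29	36	2	45.61	-1.00
BP24	14	1593.80	5.79	-0.071	104.29	43	0	23.04	0.00
BP25	12	1406.60	6.07	-0.550	97.50	50	1	25.22	0.00
BP1.5	12	1410.55	8.75	-1.658	65.00	58	1	69.98	1.09
BP2.5	12	1268.43	3.80	0.792	121.67	25	2	18.14	-1.00
BP3.5	12	1196.33	5.32	0.192	105.83	33	1	-11.27	-0.91
BP4.5	12	1389.61	8.47	-0.700	97.50	50	1	33.10	1.00
BP5.5	12	1555.80	9.70	-1.233	65.00	58	2	29.87	2.00
BP6.5	12	1255.43	4.56	-0.567	105.83	42	0	-0.98	-1.00
BP7.5	11	1081.19	5.52	0.718	97.27	36	1	30.10	0.00
BP8.5	11	1101.22	4.37	-0.155	97.27	45	0	0.95	-1.00
BP9.5	12	1478.67	4.56	-0.425	105.00	42	2	-19.12	-1.00
BP10.5	11	1252.39	6.85	-1.327	80.00	55	1	1.37	0.09
BP11.5	12	1352.65	12.01	0.008	154.17	42	0	56.56	3.00
BP12.5	11	1161.30	5.96	-0.945	53.64	45	0	59.74	0.00
BP13.5	11	1268.40	8.75	-1.173	80.00	64	1	150.45	1.09
BP14.5	12	1424.59	4.51	0.192	73.33	42	2	36.15	-1.91
BP15.5	11	1301.50	4.00	1.064	132.73	27	3	-4.57	-1.00
BP16.5	12	1358.47	5.74	-1.225	65.00	50	0	71.60	0.00
BP17.5	12	1334.49	4.00	0.333	145.83	42	1	18.14	-1.00
BP18.5	11	1224.40	5.84	-0.073	89.09	27	1	-5.48	0.00
BP19.5	10	1383.63	8.57	-0.508	117.00	50	0	32.68	0.95
BP20.5	12	1426.46	4.03	-1.542	97.50	50	1	48.99	1.09
BP21.5	12	1375.62	4.03	0.291	32.50	50	2	-0.67	-2.00
BP22.5	11	1115.31	8.64	-0.150	70.91	45	2	47.61	-2.00
BP19.5N	6	656.74	5.96	-0.183	130.00	50	0	8.33	0.00
BP19.5C	6	703.85	8.22	-0.017	130.00	50	0	47.80	0.95
BP6N	6	730.90	8.59	-0.500	130.00	50	0	58.38	1.00
BP6M	6	687.75	3.80	-0.067	146.67	50	0	40.43	-2.00
BP6C	6	686.85	8.64	-0.200	146.67	50	0	-19.97	1.00
BP7N	6	628.68	3.56	-0.117	130.00	33	0	-4.23	-2.00
BP7M	6	574.63	3.80	0.433	130.00	17	0	14.75	-1.00
BP7C	6	622.72	5.52	1.483	113.33	17	1	-5.82	0.00
BP9N	6	585.66	5.84	-0.883	65.00	33	0	-10.38	0.00
BP9M	6	643.78	6.00	0.850	161.67	33	0	-24.77	0.00
BP9C	6	695.73	4.21	-1.400	48.33	50	1	-10.62	-1.00
BP10N	6	800.96	6.10	0.550	161.67	33	1	-16.72	0.00
BP10M	6	600.71	4.00	2.050	195.00	17	0	8.33	-1.00
BP10C	6	668.71	6.85	-2.117	16.67	50	1	8.33	0.09
BP11N	6	658.75	5.84	-0.383	130.00	50	0	-5.82	0.00
BP11M	6	741.89	9.75	0.333	195.00	50	0	102.13	1.00
BP11C	6	684.84	9.75	0.617	195.00	33	0	3.85	1.00
BP12N	6	571.67	5.52	1.250	178.33	17	0	-30.87	0.00
BP12M	6	628.77	11.00	-0.200	113.33	33	0	20.22	2.00
BP12C	6	717.74	5.96	-3.217	0.00	83	0	80.62	0.00
BP13N	6	576.67	3.80	0.900	98.33	17	0	28.90	-1.00
BP13M	6	515.57	5.57	1.000	115.00	17	0	-5.82	0.00
BP13C	6	688.74	6.00	-1.000	81.67	67	0	154.80	0.00
BP14N	6	684.75	8.49	-1.283	65.00	67	1	121.03	1.09
BP14M	6	645.71	4.00	0.500	146.67	50	0	145.77	-1.00
BP14C	6	723.84	4.00	0.667	81.67	33	1	15.38	-1.00
BP15N	6	718.76	5.24	-0.283	65.00	50	1	55.25	-0.91
BP15M	6	748.84	6.46	0.017	48.33	17	2	23.15	0.09
BP15C	6	782.93	4.00	1.633	178.33	17	1	8.33	-1.00
BP22N	6	748.75	4.37	-2.267	0.00	67	1	15.38	-1.00
BP22M	6	776.84	4.37	-1.350	65.00	67	1	1.23	-1.00
BP22C	6	739.88	5.80	0.167	65.00	50	1	26.28	0.00
BP7R1	12	1233.38	3.56	0.683	121.67	25	1	15.07	-2.00
BP7R2	12	1233.38	3.56	0.683	121.67	25	1	18.14	-2.00
BP10R1	14	1621.86	6.73	-0.243	104.29	36	2	49.77	0.09
BP10R2	14	1621.86	6.80	-0.243	104.29	36	2	33.89	0.09
BP13R1	12	1247.39	4.37	-0.050	90.00	42	0	19.45	-1.00
BP13R2	12	1247.39	4.37	-0.050	90.00	42	0	-18.34	-1.00
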