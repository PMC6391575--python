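RF00994	mir-1255	2461	microRNA mir-1255	Griffiths-Jones SR	Predicted; WAR	50.00	50.10	49.90	\N	\N	0	1	0.59	seed	microRNA
RF00129	mir-103	1790	mir-103/107 microRNA precursor	Griffiths-Jones SR	Griffiths-Jones SR	60.00	60.70	59.60	\N	\N	0	1	0.59	seed	microRNA
RF00103	mir-1	1774	mir-1 microRNA precursor family	Griffiths-Jones SR	Griffiths-Jones SR	75.00	75.10	74.80	\N	\N	0	1	0.59	seed	microRNA
RF00446	mir-133	1997	mir-133 microRNA precursor family	Griffiths-Jones SR	INFERNAL	63.00	63.20	62.60	\N	mir-133a	0	1	0.59	seed	microRNA
RF00651	mir-21	2131	microRNA mir-21	Griffiths-Jones SR	miRBase; Wilkinson A	85.00	85.30	84.60	\N	\N	0	1	0.59	seed	microRNA
RF00027	let-7	1339	let-7 microRNA precursor	Griffiths-Jones SR	Griffiths-Jones SR	49.00	49.20	48.80	\N	\N	0	1	0.59	seed	microRNA
RF00019	Y_RNA	1845	Y RNA	Griffiths-Jones SR	Griffiths-Jones SR	38.00	38.10	37.90	\N	Y1,Y2,Y3,Y5	0	1	0.59	seed	Gene
RF00875	mir-485	2251	microRNA mir-485	Wilkinson A	miRBase	74.00	74.40	73.50	\N	\N	0	1	0.59	seed	microRNA
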