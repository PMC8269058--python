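# Disulfide-bridged species identified in the tryptic/chymotryptic digests of
# the four Tetranychus urticae odorant-binding proteins (in-paper evidence).
# Spans are 1-based inclusive positions in the host protein; mods use
# "<a|b>:<pos>:<name>" with peptide-local 1-based positions; aspecific=y marks
# species with one non-enzymatic terminus; software: bpf=BioPharma Finder,
# plink=pLink, both=both programs. m/z columns are experimental/theoretical
# values of the parent ion at each charge state (blank where not observed).
protein	pep_a	span_a	pep_b	span_b	mods	cys_a	cys_b	aspecific	mh1_exp	mh1_theor	mh2_exp	mh2_theor	mh3_exp	mh3_theor	mh4_exp	mh4_theor	software
TurtOBP1	CPQLEPK	57-63	HISMICGIQIVGTGY	170-184	-	57	175	n	2403.1882	2403.1868			801.7346	801.7341			plink
TurtOBP1	CPQLEPK	57-63	CGIQIVGTGY	175-184	-	57	175	y	1821.8867	1821.8873	911.4472	911.4476	607.9676	607.9676			plink
TurtOBP1	TCLK	76-79	CALNAENW	102-109	-	77	102	n	1381.6216	1381.6247	691.3147	691.3162	461.2124	461.2134			bpf
TurtOBP1	TCLK	76-79	CALNAENW	102-109	b:4:deam	77	102	n	1382.6097	1382.6078	691.8088	691.8078	461.5411	461.5418			plink
TurtOBP1	TCLK	76-79	TEVAKCAL	97-104	-	77	102	n	1295.6678	1295.6697	648.3378	648.3388	432.5611	432.5617			plink
TurtOBP1	QHSECR	141-146	QACMDY	164-169	-	145	166	y	1486.5510	1486.5507	743.7794	743.7792					plink
TurtOBP1	IVNQHSECR	138-146	QACMDY	164-169	-	145	166	y	1812.7500	1812.7461	906.8789	906.8770					plink
TurtOBP1	IVNQHSECR	138-146	QACM	164-167	-	145	166	y	1534.6561	1534.6559	767.8320	767.8318					plink
TurtOBP2	CPQLEPTNEEK	56-66	ISEVCGIEV	174-182	-	56	178	y	2233.0366	2233.0362	1117.0222	1117.0220	745.0174	745.0173			both
TurtOBP2	CPQLEPTNEEK	56-66	ISEVCGIEVQIAGSEGSSE	174-192	-	56	178	n	3178.4373	3178.4401			1060.1510	1060.1519	795.3652	795.3659	both
TurtOBP2	CPQLEPTNEEK	56-66	FISEVCGIEV	173-182	-	56	178	y	2380.1051	2380.1046	1190.5564	1190.5562	794.0402	794.0401			both
TurtOBP2	CPQLEPTNEEK	56-66	FISEVCGIEVQIAGSEGSSE	173-192	-	56	178	n	3325.5078	3325.5085			1109.1745	1109.1747	832.1328	832.1330	both
TurtOBP2	CPQLEPTNEEK	56-66	ISEVCGI	174-180	-	56	178	y	2004.9254	2004.9252	1002.9666	1002.9665	668.9803	668.9803			plink
TurtOBP2	CL	76-77	EQVAACALR	96-104	-	76	101	n	1192.5815	1192.5818	596.7946	596.7948	398.1990	398.1991			bpf
TurtOBP2	CL	76-77	EQVAACAL	96-103	-	76	101	n	1036.4800	1036.4808	518.7439	518.7443					bpf
TurtOBP2	CLESTPVPVNITR	76-88	EQVAACALR	96-104	-	76	101	n	2386.2189	2386.2216			796.0782	796.0791	597.3106	597.3112	both
TurtOBP2	CLESTPVPV	76-84	CALR	101-104	-	76	101	y	1403.7005	1403.7021	702.3542	702.3550					plink
TurtOBP2	CLESTPVPVNI	76-86	CALR	101-104	-	76	101	y	1630.8297	1630.8290			544.2818	544.2815			plink
TurtOBP2	CLESTPVPV	76-84	EQVAACALR	96-104	-	76	101	y	1901.9430	1901.9459	951.4754	951.4768					plink
TurtOBP2	CLESTPVPVNI	76-86	EQVAACALR	96-104	-	76	101	y	2129.0691	2129.0728	1065.0384	1065.0403					plink
TurtOBP2	CLESTPVPV	76-84	ACALR	100-104	-	76	101	y	1474.7363	1474.7392	737.8720	737.8735					plink
TurtOBP2	CLESTPVPV	76-84	AACALR	99-104	-	76	101	y	1545.7779	1545.7763	773.3928	773.3920					plink
TurtOBP2	QCKDEAEEK	143-151	QACMDY	167-172	-	144	169	n	1806.6951	1806.6978	903.8514	903.8528	602.9036	602.9045	452.4296	452.4303	both
TurtOBP2	QCKDEAEEK	143-151	QACMDY	167-172	a:1:pglu	144	169	n	1789.6730	1789.6713	895.3404	895.3396					plink
TurtOBP2	QCKDEAEEK	143-151	QACMDYF	167-173	-	144	169	n	1953.7656	1953.7662	977.3867	977.3870	651.9271	651.9273	489.1972	489.1974	both
TurtOBP2	QCKDEAEEK	143-151	QACMDYF	167-173	a:1:pglu	144	169	n	1936.7390	1936.7397	968.8734	968.8738					plink
TurtOBP3	CPQLEPVESDK	30-40	HISQICGITIV	143-153	-	30	148	y	2425.2093	2425.2107	1213.1086	1213.1092	890.0750	890.0754			bpf
TurtOBP3	GKCPQLEPVESDKK	28-41	HISQICGITIVGPSSPQ	143-159	-	30	148	n	3291.6762	3291.6719			1097.8973	1097.8958			bpf
TurtOBP3	CPQLEPVESDKKA	30-42	HISQICGI	143-150	-	30	148	y	2311.1390	2311.1420	1156.0734	1156.0749					plink
TurtOBP3	CPQL	30-33	HISQICGITIVGPSSPQ	143-159	-	30	148	n	2194.0910	2194.0994			732.0355	732.0383			plink
TurtOBP3	CPQL	30-33	HISQICGI	143-150	-	30	148	y	1327.6504	1327.6496			443.2220	443.2217			plink
TurtOBP3	ADIISSCLK	44-52	CAL	75-77	-	50	75	n	1252.6273	1252.6278	626.8176	626.8178	418.2143	418.2145			bpf
TurtOBP3	ADIISSCLK	44-52	CALNAENW	75-82	-	50	75	n	1866.8713	1866.8724	933.9396	933.9401					plink
TurtOBP3	ADIISSCLK	44-52	CALNAENWFTEDGK	75-88	-	50	75	n	2544.1722	2544.1744			848.7293	848.7300			plink
TurtOBP3	ADIISSCLK	44-52	CALNAENWF	75-83	-	50	75	n	2013.9395	2013.9408	1007.4736	1007.4743					plink
TurtOBP3	ADIISSCL	44-51	CAL	75-77	-	50	75	n	1124.5314	1124.5328	562.7696	562.7703					bpf
TurtOBP3	QHGECR	114-119	QACMDY	137-142	-	118	139	n	1456.5387	1456.5402	728.7732	728.7740					both
TurtOBP3	QHGECR	114-119	QACMDY	137-142	a:1:pglu	118	139	n	1439.5121	1439.5136	720.2600	720.2607					plink
TurtOBP3	QHGECR	114-119	CMDY	139-142	a:1:pglu	118	139	y	1240.4181	1240.4179	620.7130	620.7128					plink
TurtOBP3	QHGECR	114-119	YQACMDY	136-142	-	118	139	n	1619.6010	1619.6035	810.3044	810.3056					plink
TurtOBP4	CPQLEPK	41-47	HISQICGITIV	154-164	-	41	159	n	1995.0406	1995.0401	998.0242	998.0240	665.6854	665.6852	499.5160	499.5159	both
TurtOBP4	CPQLEPK	41-47	HISQICGITIVGASSPQ	154-170	-	41	159	n	2522.2745	2522.2740			841.4300	841.4299	631.3245	631.3244	both
TurtOBP4	GKCPQLEPK	39-47	HISQICGITIVGASSPQ	154-170	-	41	159	n	2707.3918	2707.3904			903.1358	903.1354	677.6038	677.6035	both
TurtOBP4	CPQLEPK	41-47	HISQICG	154-160	-	41	159	y	1568.7546	1568.7559	784.8812	784.8819	523.5901	523.5905			both
TurtOBP4	GKCPQLEPK	39-47	HISQICGI	154-161	-	41	159	y	1866.9556	1866.9564	933.9817	933.9821	622.9904	622.9907			both
TurtOBP4	ADIISSCIK	55-63	TEVAICAL	81-88	-	61	86	n	1765.9071	1765.9074	883.4575	883.4576	589.3076	589.3077			both
TurtOBP4	ADIISSCIK	55-63	AICAL	84-88	-	61	86	n	1436.7488	1436.7487	718.8783	718.8783	479.5881	479.5881			both
TurtOBP4	ADIISSCIK	55-63	HRTEVAICAL	79-88	-	61	86	n	2059.0686	2059.0674	1030.0382	1030.0376			515.5230	515.5227	both
TurtOBP4	AKADIISSCIK	53-63	HRTEVAICAL	79-88	-	61	86	n	2258.1979	2258.1994			753.4045	753.4050	565.3053	565.3057	plink
TurtOBP4	AKADIISSCIK	53-63	TEVAICAL	81-88	-	61	86	n	1965.0404	1965.0394			655.6853	655.6850			plink
TurtOBP4	ADIISSCIK	55-63	TEVAICA	81-87	-	61	86	y	1652.8223	1652.8233	826.9151	826.9156					both
TurtOBP4	ADIISSCIK	55-63	RTEVAICAL	80-88	-	61	86	y	1922.0080	1922.0084	961.5079	961.5081	641.3412	641.3414			both
TurtOBP4	QHGECR	125-130	YQACMDY	147-153	-	129	150	n	1619.6036	1619.6035	810.3057	810.3057					both
TurtOBP4	QHGECR	125-130	YQACMDY	147-153	a:1:pglu	129	150	n	1602.5761	1602.5769	801.7920	801.7924					plink
TurtOBP4	QHGECR	125-130	QACMDY	148-153	-	129	150	n	1456.5378	1456.5402	728.7728	728.7740					both
TurtOBP4	QHGECR	125-130	QACMDY	148-153	a:1:pglu	129	150	n	1439.5138	1439.5136	720.2608	720.2607					plink
TurtOBP4	QHGECR	125-130	ACMDY	149-153	-	129	150	y	1328.4796	1328.4816	664.7437	664.7447					both
TurtOBP4	QHGECR	125-130	ACMDY	149-153	a:1:pglu	129	150	y	1311.4549	1311.4550	656.2314	656.2314					plink
TurtOBP4	QHGECR	125-130	QACMDYHISQ	148-157	-	129	150	y	1921.7751	1921.7737	961.3915	961.3908					plink
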