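chrom	pos	p_dosage_e6	p_best_guess_e6	quality_initial	quality_min	typed
1	205680881	2.28	4.04	0.935	0.895	0
1	205717676	2.18	1.41	0.966	0.954	0
1	205719191	1.85	1.07	0.971	0.966	0
1	205719513	2.84	1.81	0.948	0.913	0
1	205728574	2.27	2.61	0.969	0.965	0
1	205735864	2.32	2.28	0.968	0.964	0
1	205737511	2.40	2.61	0.968	0.965	0
1	210978952	12.44	4.73	0.844	0.603	0
2	97014837	2.97	1.53	0.971	0.956	0
2	102161388	1.22	1.22	0.947	0.911	0
2	102162574	2.85	1.60	0.945	0.925	0
2	102170710	1.68	0.69	0.943	0.920	0
2	102172703	1.89	1.49	0.939	0.910	0
2	102173795	1.89	1.49	0.939	0.910	0
2	102174383	1.89	1.49	0.939	0.910	0
2	102175042	1.89	1.49	0.939	0.910	0
2	102175179	1.89	1.49	0.939	0.910	0
2	102177233	0.134	0.96	0.832	0.772	0
2	102177394	1.83	1.66	0.936	0.901	0
2	102177774	1.82	1.66	0.936	0.901	0
2	102177908	1.82	1.66	0.936	0.901	0
2	102177980	1.82	1.66	0.936	0.901	0
2	102178199	1.84	1.66	0.936	0.901	0
2	204723052	4.86	12.37	0.952	0.924	0
2	240877081	5.73	4.14	0.915	0.897	0
4	141091361	4.75	4.75	NA	NA	1
4	141104884	3.78	5.84	0.962	0.952	0
4	141110792	4.15	4.75	0.969	0.960	0
4	141111464	3.56	4.75	0.965	0.956	0
4	141117653	4.13	4.75	0.968	0.960	0
4	141120663	3.77	2.19	0.969	0.963	0
4	141121085	3.77	2.19	0.969	0.963	0
4	141125645	3.78	2.19	0.969	0.962	0
4	141128772	3.82	2.19	0.969	0.962	0
4	141132155	3.77	2.19	0.969	0.963	0
4	141136738	3.77	2.19	0.955	0.916	0
4	141138951	5.48	3.79	0.954	0.916	0
4	141141924	2.54	1.47	0.954	0.915	0
4	141150956	2.23	1.47	0.956	0.923	0
4	141152718	5.87	4.72	0.953	0.921	0
5	124428561	1.62	8.65	0.885	0.849	0
6	43842319	1.30	3.68	0.817	0.704	0
6	130733300	4.65	>100	0.659	0.238	0
10	28800202	3.00	2.70	0.959	0.957	0
10	28801273	3.01	2.70	0.959	0.957	0
10	28805472	3.40	3.40	NA	NA	1
10	28821444	2.33	2.27	0.953	0.95	0
10	28830108	3.23	2.80	0.953	0.949	0
10	28832820	3.23	2.80	0.953	0.949	0
10	28843854	3.23	2.80	0.953	0.949	0
10	28862152	3.02	3.12	0.952	0.946	0
10	28869729	3.61	3.82	0.953	0.947	0
10	28880160	2.93	3.12	0.952	0.946	0
10	28880992	2.93	3.12	0.952	0.946	0
10	28886537	2.69	2.63	0.956	0.950	0
10	28886626	2.69	2.63	0.956	0.950	0
10	28891174	2.69	2.63	0.956	0.950	0
10	28893554	2.67	2.63	0.956	0.950	0
10	28894110	3.24	3.31	0.956	0.950	0
10	28894247	2.67	2.63	0.956	0.950	0
10	28905079	2.62	2.63	0.956	0.949	0
10	28913309	4.10	4.10	NA	NA	1
12	116890740	4.99	4.25	0.838	0.554	0
13	40886155	0.433	7.51	0.695	0.546	0
14	80936831	3.95	4.82	0.952	0.947	0
14	80947552	4.50	5.60	0.954	0.948	0
14	80947648	3.69	4.73	0.958	0.941	0
14	80947818	3.68	4.73	0.95	0.941	0
14	80948392	3.64	4.73	0.95	0.941	0
14	80949372	3.62	4.58	0.95	0.940	0
17	80667812	7.34	2.63	0.958	0.900	0
17	80668325	5.33	2.27	0.960	0.901	0
17	80668375	5.42	2.27	0.961	0.901	0
17	80668985	5.40	2.27	0.961	0.901	0
17	80669238	5.31	2.27	0.960	0.901	0
17	80670820	5.31	2.27	0.960	0.901	0
17	80670873	5.32	2.27	0.960	0.901	0
17	80671047	5.32	2.27	0.960	0.901	0
20	18926221	1.74	0.78	0.642	0.518	0
20	18954449	5.17	1.51	0.642	0.514	0
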