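atom_index	element	q_neutral	q_anion	q_cation
1	O	-0.099	-0.099	-0.095
2	O	-0.258	-0.271	-0.228
3	O	-0.227	-0.236	-0.207
4	N	-0.104	-0.106	0.070
5	C	0.019	0.015	0.036
6	C	0.018	0.013	0.036
7	C	-0.064	-0.072	-0.041
8	C	-0.065	-0.074	-0.042
9	C	-0.067	-0.072	-0.057
10	C	-0.064	-0.069	-0.053
11	C	0.055	0.053	0.056
12	C	-0.053	-0.070	-0.014
13	C	0.207	0.201	0.216
14	C	-0.029	-0.034	-0.022
15	C	-0.003	-0.007	0.021
16	C	0.017	0.009	0.029
17	C	-0.046	-0.062	-0.021
18	C	-0.044	-0.050	-0.034
19	C	-0.043	-0.064	-0.019
20	C	-0.042	-0.058	-0.019
21	C	-0.045	-0.064	0.002
22	H	0.037	0.011	0.059
23	H	0.037	-0.007	0.059
24	H	0.035	0.023	0.060
25	H	0.029	-0.013	0.050
26	H	0.029	-0.026	0.050
27	H	0.032	0.015	0.057
28	H	0.034	0.021	0.055
29	H	0.032	0.016	0.045
30	H	0.036	0.023	0.047
31	H	0.033	0.012	0.055
32	H	0.032	0.028	0.040
33	H	0.036	-0.002	0.067
34	H	0.035	-0.010	0.067
35	H	0.020	-0.026	0.074
36	H	0.052	0.014	0.063
37	H	0.028	-0.002	0.042
38	H	0.042	0.028	0.054
39	H	0.042	-0.035	0.057
40	H	0.042	0.032	0.048
41	H	0.138	0.127	0.145
42	H	0.045	-0.032	0.064
43	H	0.046	0.011	0.061
44	H	0.045	-0.001	0.067
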