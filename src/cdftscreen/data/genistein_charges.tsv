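atom_index	element	q_neutral	q_anion	q_cation
1	O	-0.066	-0.115	-0.024
2	O	-0.182	-0.227	-0.127
3	O	-0.237	-0.339	-0.211
4	O	-0.170	-0.207	-0.137
5	O	-0.183	-0.208	-0.114
6	C	-0.064	-0.073	-0.050
7	C	-0.033	-0.078	0.001
8	C	0.082	0.068	0.095
9	C	0.119	0.025	0.128
10	C	-0.018	-0.006	0.028
11	C	0.094	0.054	0.127
12	C	0.064	-0.052	0.109
13	C	-0.091	-0.127	-0.021
14	C	-0.095	-0.131	-0.054
15	C	0.086	0.040	0.114
16	C	-0.033	-0.040	0.002
17	C	-0.040	-0.051	-0.010
18	C	-0.068	-0.088	-0.028
19	C	-0.060	-0.082	-0.014
20	C	0.071	0.043	0.127
21	H	0.064	0.006	0.087
22	H	0.057	0.029	0.086
23	H	0.049	0.021	0.075
24	H	0.045	0.039	0.065
25	H	0.042	0.030	0.063
26	H	0.044	0.025	0.070
27	H	0.051	0.032	0.079
28	H	0.121	0.102	0.136
29	H	0.178	0.156	0.198
30	H	0.173	0.156	0.201
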