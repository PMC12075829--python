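atom_index	element	f_minus	f_plus	f_zero	cdd
1	O	0.042	0.050	0.046	0.008
2	O	0.055	0.045	0.050	-0.010
3	O	0.026	0.102	0.064	0.076
4	O	0.033	0.037	0.035	0.005
5	O	0.068	0.025	0.047	-0.043
6	C	0.013	0.009	0.011	-0.004
7	C	0.034	0.045	0.039	0.011
8	C	0.013	0.015	0.014	0.002
9	C	0.009	0.093	0.051	0.084
10	C	0.046	-0.011	0.017	-0.057
11	C	0.032	0.041	0.036	0.009
12	C	0.045	0.116	0.081	0.071
13	C	0.071	0.035	0.053	-0.036
14	C	0.042	0.036	0.039	-0.006
15	C	0.028	0.046	0.037	0.017
16	C	0.035	0.007	0.021	-0.028
17	C	0.031	0.010	0.020	-0.021
18	C	0.040	0.020	0.030	-0.019
19	C	0.046	0.022	0.034	-0.024
20	C	0.056	0.028	0.042	-0.028
21	H	0.022	0.058	0.040	0.036
22	H	0.029	0.027	0.028	-0.002
23	H	0.025	0.029	0.027	0.004
24	H	0.020	0.006	0.013	-0.014
25	H	0.021	0.012	0.016	-0.009
26	H	0.027	0.019	0.023	-0.008
27	H	0.028	0.019	0.024	-0.009
28	H	0.015	0.019	0.017	0.004
29	H	0.020	0.022	0.021	0.003
30	H	0.029	0.017	0.023	-0.012
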