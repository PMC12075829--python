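atom_index	element	f_minus	f_plus	f_zero	cdd
1	O	0.005	0.000	0.002	-0.005
2	O	0.030	0.013	0.022	-0.017
3	O	0.020	0.009	0.015	-0.011
4	N	0.174	0.001	0.088	-0.173
5	C	0.017	0.004	0.011	-0.013
6	C	0.018	0.005	0.011	-0.013
7	C	0.023	0.008	0.016	-0.015
8	C	0.023	0.010	0.016	-0.014
9	C	0.011	0.004	0.007	-0.006
10	C	0.011	0.005	0.008	-0.007
11	C	0.001	0.001	0.001	0.000
12	C	0.039	0.018	0.028	-0.021
13	C	0.009	0.005	0.007	-0.004
14	C	0.007	0.005	0.006	-0.003
15	C	0.024	0.004	0.014	-0.020
16	C	0.012	0.008	0.010	-0.004
17	C	0.025	0.017	0.021	-0.008
18	C	0.010	0.006	0.008	-0.004
19	C	0.024	0.021	0.022	-0.003
20	C	0.023	0.016	0.019	-0.008
21	C	0.047	0.019	0.033	-0.028
22	H	0.022	0.026	0.024	0.004
23	H	0.021	0.044	0.033	0.023
24	H	0.025	0.012	0.018	-0.013
25	H	0.021	0.042	0.031	0.021
26	H	0.021	0.055	0.038	0.034
27	H	0.025	0.017	0.021	-0.008
28	H	0.021	0.013	0.017	-0.009
29	H	0.012	0.017	0.015	0.004
30	H	0.011	0.012	0.012	0.001
31	H	0.021	0.021	0.021	-0.001
32	H	0.008	0.004	0.006	-0.004
33	H	0.032	0.037	0.035	0.006
34	H	0.031	0.046	0.039	0.014
35	H	0.054	0.047	0.050	-0.007
36	H	0.010	0.039	0.024	0.028
37	H	0.014	0.030	0.022	0.016
38	H	0.012	0.014	0.013	0.002
39	H	0.015	0.077	0.046	0.062
40	H	0.006	0.010	0.008	0.003
41	H	0.008	0.011	0.009	0.003
42	H	0.018	0.077	0.048	0.059
43	H	0.016	0.035	0.025	0.019
44	H	0.022	0.046	0.034	0.024
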