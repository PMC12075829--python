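pose_id	genistein_site	hyoscyamine_site	bond_label	pre_opt_length	post_opt_length	donor_element	acceptor_element
01	C20-O5-H30	C13=O2	H30...O2	1.43797	1.77254	H	O
02	C15-O4-H29	C13=O2	H29...O2	1.495	1.68825	H	O
03	C12<->H21	C16-O3H41	C12...O3	2.23484	3.15105	C	O
04	C20-O5-H30	C16-O3H41	H30...O3	0.83703	1.72131	H	O
05	C15-O4-H29	C16-O3H41	H29...O3	0.92281	1.66516	H	O
06	C12<->H21	C13=O2	C12...O2	1.06519	3.23151	C	O
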