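# surrogate_cas12a position-weight table, version 1
position	A	C	G	T
0	-0.483207	-0.224318	0.608775	-0.150622
1	0.306405	-0.009433	0.437094	-0.194830
2	-0.153763	-0.212241	-0.402904	0.232920
3	-0.126380	-0.426960	-0.682256	-0.443793
4	-0.380072	-0.202272	-0.243256	0.176118
5	-0.308549	0.274451	-0.299855	0.112019
6	0.968240	-0.232301	0.437188	-0.364190
7	0.099939	-0.182165	-0.269489	0.572138
8	-0.202252	-0.169970	0.108785	-0.282930
9	0.099978	0.010093	-0.446694	-0.256903
10	-0.531763	-0.148736	-0.384356	-0.257555
11	-0.180660	0.232217	0.023998	0.563556
12	0.354739	-0.193714	-0.069875	0.037886
13	0.030326	-0.361928	0.553558	-0.436121
14	-0.090434	-0.056347	0.013055	-0.348457
15	0.154884	0.700500	0.184307	-0.266392
16	-0.322807	0.028419	0.245854	-0.330316
17	0.062382	-0.231821	0.895294	0.147734
18	-0.208688	0.022087	-0.358140	0.220905
19	0.063830	0.213488	-0.030390	0.540788
20	-0.182357	-0.652435	-0.026685	0.029768
21	0.359020	0.003745	-0.098734	0.381512
22	0.126223	0.338774	0.432469	0.054125
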