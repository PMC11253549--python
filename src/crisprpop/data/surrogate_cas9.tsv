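# surrogate_cas9 position-weight table, version 1
position	A	C	G	T
0	-0.091747	-0.127408	0.304920	-0.109273
1	0.242912	0.232432	-0.194696	0.227012
2	0.173274	-0.269539	0.185859	0.391772
3	0.118963	-0.061077	0.285793	-0.189850
4	-0.008529	0.691344	0.598588	-0.310496
5	0.080097	0.545445	-0.408598	0.527543
6	-0.346801	0.333098	-0.144640	0.273136
7	0.217330	0.238556	0.560951	-0.373733
8	0.034197	-0.016341	0.168108	-0.162737
9	0.014849	0.334923	-0.257664	0.446309
10	0.124806	0.275098	0.030195	0.062789
11	-0.240209	0.214847	0.355833	0.080835
12	0.157774	0.946068	0.176639	0.111245
13	0.150392	0.388398	0.360367	-0.028613
14	0.416781	0.085662	0.049377	-0.196200
15	0.386318	0.006623	-0.463669	0.126157
16	-0.000524	0.414836	0.052823	-0.177875
17	-0.368250	0.158172	-0.050914	-0.144942
18	0.196184	-0.625676	-0.271521	0.575289
19	-0.214185	-0.213409	0.416000	-0.053546
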