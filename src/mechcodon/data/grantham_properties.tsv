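# Amino-acid property values of Grantham (1974), Science 185:862-864, Table 1.
# columns: one-letter code, composition c, polarity p, molecular volume v
A	0.0	8.1	31.0
C	2.75	5.5	55.0
D	1.38	13.0	54.0
E	0.92	12.3	83.0
F	0.0	5.2	132.0
G	0.74	9.0	3.0
H	0.58	10.4	96.0
I	0.0	5.2	111.0
K	0.33	11.3	119.0
L	0.0	4.9	111.0
M	0.0	5.7	105.0
N	1.33	11.6	56.0
P	0.39	8.0	32.5
Q	0.89	10.5	85.0
R	0.65	10.5	124.0
S	1.42	9.2	32.0
T	0.71	8.6	61.0
V	0.0	5.9	84.0
W	0.13	5.4	170.0
Y	0.2	6.2	136.0
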