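channel	minus2	minus1	plus1	plus2
126	0.0	0.0	4.7	0.0
127N	0.0	0.2	5.9	0.0
127C	0.0	0.3	4.4	0.0
128N	0.0	0.4	4.2	0.0
128C	0.1	0.6	3.3	0.0
129N	0.1	0.8	3.5	0.0
129C	0.1	1.4	2.4	0.0
130N	0.2	1.5	2.6	0.0
130C	0.1	1.8	2.1	0.0
131	0.2	2.3	1.7	0.0
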