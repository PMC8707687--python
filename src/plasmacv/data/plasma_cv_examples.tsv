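accession	description	cv_total	cv_analytical	cv_biological
P17936	Insulin-like growth factor-binding protein 3	15.0	4.0	14.4
P02647	Apolipoprotein A-I	13.0	2.3	12.8
P01034	Cystatin-C	16.3	6.6	14.9
P05543	Thyroxine-binding globulin	9.4	3.3	8.8
P01024	Complement C3	10.0	1.8	9.8
P02766	Transthyretin	18.2	10.6	14.7
P04114	Apolipoprotein B-100	23.3	1.7	23.2
P19652	Alpha-1-acid glycoprotein 2	37.4	10.7	35.8
P02763	Alpha-1-acid glycoprotein 1	24.6	6.2	23.8
P0C0L4	Complement C4-A	25.4	7.6	24.2
P0C0L5	Complement C4-B	23.8	11.2	21.0
P04278	Sex hormone-binding globulin	22.1	6.2	21.2
P00738	Haptoglobin	38.3	2.7	38.2
P02768	Serum albumin	7.1	1.9	6.8
Q15848	Adiponectin	23.9	12.6	20.3
P01009	Alpha-1-antitrypsin	13.7	2.8	13.4
P02741	C-reactive protein	92.3	7.6	92.0
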