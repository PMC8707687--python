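accession	description	eflm_cv_biological	meta_analysis	comparable
P17936	Insulin-like growth factor-binding protein 3	0.003	False	False
P02647	Apolipoprotein A-I	11.2	True	True
P01034	Cystatin-C	12.1	True	True
P05543	Thyroxine-binding globulin	12.6	False	True
P01024	Complement C3	15.2	True	True
P02766	Transthyretin	19.1	True	True
P04114	Apolipoprotein B-100	20.2	True	True
P19652	Alpha-1-acid glycoprotein 2	24.1	True	True
P02763	Alpha-1-acid glycoprotein 1	24.1	True	True
P0C0L4	Complement C4-A	24.5	True	True
P0C0L5	Complement C4-B	24.5	True	True
P04278	Sex hormone-binding globulin	35.6	True	True
P00738	Haptoglobin	39.0	True	True
P02768	Serum albumin	5.1	True	True
Q15848	Adiponectin	51.2	True	True
P01009	Alpha-1-antitrypsin	10.5	True	True
P02741	C-reactive protein	87.7	True	True
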