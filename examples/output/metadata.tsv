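sample	time	replicate
S1	0.0	1
S2	0.0	2
S3	0.10563086423129525	1
S4	0.10563086423129525	2
S5	0.19285530415379942	1
S6	0.19285530415379942	2
S7	0.19466092409894697	1
S8	0.19466092409894697	2
S9	0.206952109300433	1
S10	0.206952109300433	2
S11	0.2218891268661839	1
S12	0.2218891268661839	2
S13	0.41296322364169397	1
S14	0.41296322364169397	2
S15	0.5534896855946865	1
S16	0.5534896855946865	2
S17	0.7489167936601724	1
S18	0.7489167936601724	2
S19	0.7670850327048939	1
S20	0.7670850327048939	2
S21	0.7685734702247407	1
S22	0.7685734702247407	2
S23	0.8236129033050394	1
S24	0.8236129033050394	2
S25	0.9022475364350362	1
S26	0.9022475364350362	2
S27	0.9328253891945743	1
S28	0.9328253891945743	2
S29	0.9942644287751989	1
S30	0.9942644287751989	2
S31	1.0055408761537257	1
S32	1.0055408761537257	2
S33	1.1820593917559878	1
S34	1.1820593917559878	2
S35	1.225104653954487	1
S36	1.225104653954487	2
S37	1.3923165344405541	1
S38	1.3923165344405541	2
S39	1.5	1
S40	1.5	2
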