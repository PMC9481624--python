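gene	sample	replicate	log2_rpkm
g01	MEF	1	3.0
g01	iPSC	1	1.5
g01	MEF	2	3.0
g01	iPSC	2	2.0
g01	MEF	3	3.0
g01	iPSC	3	2.0
g02	MEF	1	3.0
g02	iPSC	1	2.0
g02	MEF	2	3.0
g02	iPSC	2	2.0
g02	MEF	3	3.0
g02	iPSC	3	2.0
g03	MEF	1	3.0
g03	iPSC	1	2.0
g03	MEF	2	3.0
g03	iPSC	2	2.0
g03	MEF	3	3.0
g03	iPSC	3	2.0
g04	MEF	1	3.0
g04	iPSC	1	1.0
g04	MEF	2	3.0
g04	iPSC	2	2.0
g04	MEF	3	3.0
g04	iPSC	3	2.0
g05	MEF	1	3.0
g05	iPSC	1	2.0
g05	MEF	2	3.0
g05	iPSC	2	2.0
g05	MEF	3	3.0
g05	iPSC	3	2.0
g06	MEF	1	3.0
g06	iPSC	1	2.0
g06	MEF	2	3.0
g06	iPSC	2	2.0
g06	MEF	3	3.0
g06	iPSC	3	2.0
g07	MEF	1	3.0
g07	iPSC	1	2.0
g07	MEF	2	3.0
g07	iPSC	2	2.0
g07	MEF	3	3.0
g07	iPSC	3	2.0
g08	MEF	1	3.0
g08	iPSC	1	0.8
g08	MEF	2	3.0
g08	iPSC	2	2.0
g08	MEF	3	3.0
g08	iPSC	3	2.0
g09	MEF	1	3.0
g09	iPSC	1	2.0
g09	MEF	2	3.0
g09	iPSC	2	2.0
g09	MEF	3	3.0
g09	iPSC	3	2.0
g10	MEF	1	3.0
g10	iPSC	1	2.0
g10	MEF	2	3.0
g10	iPSC	2	2.0
g10	MEF	3	3.0
g10	iPSC	3	2.0
g11	MEF	1	3.0
g11	iPSC	1	2.0
g11	MEF	2	3.0
g11	iPSC	2	2.0
g11	MEF	3	3.0
g11	iPSC	3	2.0
g12	MEF	1	3.0
g12	iPSC	1	2.0
g12	MEF	2	3.0
g12	iPSC	2	2.0
g12	MEF	3	3.0
g12	iPSC	3	2.0
g13	MEF	1	3.0
g13	iPSC	1	2.0
g13	MEF	2	3.0
g13	iPSC	2	2.0
g13	MEF	3	3.0
g13	iPSC	3	2.0
g14	MEF	1	3.0
g14	iPSC	1	1.01
g14	MEF	2	3.0
g14	iPSC	2	1.2
g14	MEF	3	3.0
g14	iPSC	3	3.0
g15	MEF	1	3.0
g15	iPSC	1	2.0
g15	MEF	2	3.0
g15	iPSC	2	2.0
g15	MEF	3	3.0
g15	iPSC	3	2.0
g16	MEF	1	3.0
g16	iPSC	1	3.0
g16	MEF	2	3.0
g16	iPSC	2	0.9
g16	MEF	3	3.0
g16	iPSC	3	3.0
g17	MEF	1	3.0
g17	iPSC	1	2.0
g17	MEF	2	3.0
g17	iPSC	2	2.0
g17	MEF	3	3.0
g17	iPSC	3	2.0
g18	MEF	1	3.0
g18	iPSC	1	2.0
g18	MEF	2	3.0
g18	iPSC	2	2.0
g18	MEF	3	3.0
g18	iPSC	3	2.0
g19	MEF	1	3.0
g19	iPSC	1	2.0
g19	MEF	2	3.0
g19	iPSC	2	2.0
g19	MEF	3	3.0
g19	iPSC	3	2.0
g20	MEF	1	3.0
g20	iPSC	1	1.1
g20	MEF	2	3.0
g20	iPSC	2	1.1
g20	MEF	3	3.0
g20	iPSC	3	1.1
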