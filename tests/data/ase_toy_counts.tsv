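gene	chrom	expected_parent	sample	replicate	maternal_count	paternal_count
g01	chr1	maternal	MEF	1	19	1
g01	chr1	maternal	iPSC	1	4	4
g01	chr1	maternal	MEF	2	19	1
g01	chr1	maternal	iPSC	2	3	4
g01	chr1	maternal	MEF	3	19	1
g01	chr1	maternal	iPSC	3	1	1
g02	chr1	maternal	MEF	1	17	3
g02	chr1	maternal	iPSC	1	6	6
g02	chr1	maternal	MEF	2	17	3
g02	chr1	maternal	iPSC	2	6	6
g02	chr1	maternal	MEF	3	17	3
g02	chr1	maternal	iPSC	3	6	6
g03	chr2	maternal	MEF	1	24	1
g03	chr2	maternal	iPSC	1	3	2
g03	chr2	maternal	MEF	2	24	1
g03	chr2	maternal	iPSC	2	2	3
g03	chr2	maternal	MEF	3	24	1
g03	chr2	maternal	iPSC	3	4	1
g04	chr2	maternal	MEF	1	97	3
g04	chr2	maternal	iPSC	1	5	5
g04	chr2	maternal	MEF	2	97	3
g04	chr2	maternal	iPSC	2	6	6
g04	chr2	maternal	MEF	3	97	3
g04	chr2	maternal	iPSC	3	6	6
g05	chr3	maternal	MEF	1	18	2
g05	chr3	maternal	iPSC	1	6	6
g05	chr3	maternal	MEF	2	18	2
g05	chr3	maternal	iPSC	2	6	6
g05	chr3	maternal	MEF	3	18	2
g05	chr3	maternal	iPSC	3	6	6
g06	chr3	paternal	MEF	1	3	97
g06	chr3	paternal	iPSC	1	0	10
g06	chr3	paternal	MEF	2	3	97
g06	chr3	paternal	iPSC	2	0	9
g06	chr3	paternal	MEF	3	3	97
g06	chr3	paternal	iPSC	3	0	8
g07	chr4	paternal	MEF	1	19	1
g07	chr4	paternal	iPSC	1	3	7
g07	chr4	paternal	MEF	2	19	1
g07	chr4	paternal	iPSC	2	3	7
g07	chr4	paternal	MEF	3	19	1
g07	chr4	paternal	iPSC	3	3	7
g08	chr4	paternal	MEF	1	2	98
g08	chr4	paternal	iPSC	1	1	9
g08	chr4	paternal	MEF	2	2	98
g08	chr4	paternal	iPSC	2	1	9
g08	chr4	paternal	MEF	3	2	98
g08	chr4	paternal	iPSC	3	1	9
g09	chr5	paternal	MEF	1	1	19
g09	chr5	paternal	iPSC	1	6	0
g09	chr5	paternal	MEF	2	1	19
g09	chr5	paternal	iPSC	2	6	0
g09	chr5	paternal	MEF	3	1	19
g09	chr5	paternal	iPSC	3	4	0
g10	chr5	maternal	MEF	1	20	0
g10	chr5	maternal	iPSC	1	20	0
g10	chr5	maternal	MEF	2	20	0
g10	chr5	maternal	iPSC	2	18	0
g10	chr5	maternal	MEF	3	20	0
g10	chr5	maternal	iPSC	3	15	0
g11	chr6	maternal	MEF	1	23	2
g11	chr6	maternal	iPSC	1	1	1
g11	chr6	maternal	MEF	2	23	2
g11	chr6	maternal	iPSC	2	2	0
g11	chr6	maternal	MEF	3	23	2
g11	chr6	maternal	iPSC	3	5	3
g12	chr6	paternal	MEF	1	2	18
g12	chr6	paternal	iPSC	1	1	9
g12	chr6	paternal	MEF	2	2	18
g12	chr6	paternal	iPSC	2	1	9
g12	chr6	paternal	MEF	3	2	18
g12	chr6	paternal	iPSC	3	1	9
g13	chr7	none	MEF	1	10	10
g13	chr7	none	iPSC	1	5	5
g13	chr7	none	MEF	2	10	10
g13	chr7	none	iPSC	2	6	6
g13	chr7	none	MEF	3	10	10
g13	chr7	none	iPSC	3	5	5
g14	chr7	maternal	MEF	1	91	9
g14	chr7	maternal	iPSC	1	5	1
g14	chr7	maternal	MEF	2	91	9
g14	chr7	maternal	iPSC	2	4	2
g14	chr7	maternal	MEF	3	91	9
g14	chr7	maternal	iPSC	3	5	1
g15	chr8	paternal	MEF	1	0	25
g15	chr8	paternal	iPSC	1	1	6
g15	chr8	paternal	MEF	2	0	25
g15	chr8	paternal	iPSC	2	1	5
g15	chr8	paternal	MEF	3	0	25
g15	chr8	paternal	iPSC	3	0	7
g16	chr8	maternal	MEF	1	19	1
g16	chr8	maternal	iPSC	1	6	6
g16	chr8	maternal	MEF	2	19	1
g16	chr8	maternal	iPSC	2	6	6
g16	chr8	maternal	MEF	3	19	1
g16	chr8	maternal	iPSC	3	6	6
g17	chr9	paternal	MEF	1	4	96
g17	chr9	paternal	iPSC	1	0	0
g17	chr9	paternal	MEF	2	4	96
g17	chr9	paternal	iPSC	2	0	0
g17	chr9	paternal	MEF	3	4	96
g17	chr9	paternal	iPSC	3	0	0
g18	chr9	maternal	MEF	1	93	7
g18	chr9	maternal	iPSC	1	2	10
g18	chr9	maternal	MEF	2	93	7
g18	chr9	maternal	iPSC	2	1	10
g18	chr9	maternal	MEF	3	93	7
g18	chr9	maternal	iPSC	3	1	9
g19	chr10	none	MEF	1	12	13
g19	chr10	none	iPSC	1	6	6
g19	chr10	none	MEF	2	12	13
g19	chr10	none	iPSC	2	5	7
g19	chr10	none	MEF	3	12	13
g19	chr10	none	iPSC	3	6	6
g20	chr10	paternal	MEF	1	1	99
g20	chr10	paternal	iPSC	1	3	3
g20	chr10	paternal	MEF	2	1	99
g20	chr10	paternal	iPSC	2	3	4
g20	chr10	paternal	MEF	3	1	99
g20	chr10	paternal	iPSC	3	3	3
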