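population	n	locus	hom_susceptible	heterozygote	hom_resistant	frequency
Monterrey	28	410	6	11	11	0.59
Monterrey	28	1016	8	16	4	0.43
Monterrey	28	1534	0	0	28	1.00
Guadalupe	30	410	4	14	12	0.63
Guadalupe	30	1016	0	20	10	0.67
Guadalupe	30	1534	0	1	29	0.98
Poza Rica	29	410	3	7	19	0.78
Poza Rica	29	1016	20	7	2	0.19
Poza Rica	29	1534	0	0	29	1.00
Minatitlan	30	410	0	1	29	0.98
Minatitlan	30	1016	1	2	27	0.97
Minatitlan	30	1534	1	11	18	0.78
Cardel	30	410	0	3	27	0.95
Cardel	30	1016	0	3	27	0.95
Cardel	30	1534	0	0	30	1.00
Cosoleacaque	27	410	10	13	4	0.39
Cosoleacaque	27	1016	1	20	6	0.59
Cosoleacaque	27	1534	0	10	17	0.81
Villa Hermosa	30	410	1	14	15	0.73
Villa Hermosa	30	1016	1	15	14	0.72
Villa Hermosa	30	1534	0	0	30	1.00
Chiapas	29	410	2	21	6	0.57
Chiapas	29	1016	1	25	3	0.53
Chiapas	29	1534	0	6	23	0.90
Merida	30	410	3	18	9	0.60
Merida	30	1016	3	17	10	0.62
Merida	30	1534	0	0	30	1.00
San Antonio Kaua	30	410	5	10	15	0.67
San Antonio Kaua	30	1016	2	12	16	0.73
San Antonio Kaua	30	1534	0	0	30	1.00
Vergel	30	410	1	19	10	0.65
Vergel	30	1016	1	20	9	0.63
Vergel	30	1534	0	0	30	1.00
Cancun	29	410	12	13	4	0.36
Cancun	29	1016	0	12	17	0.79
Cancun	29	1534	0	2	27	0.97
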