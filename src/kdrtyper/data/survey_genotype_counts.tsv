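population	LL/II/CC	LL/VI/CC	LL/VV/CC	LL/VI/FC	VL/II/CC	VL/VI/CC	VV/II/CC	VV/VI/CC	VL/VI/FC	LL/VV/FF	VV/VI/FC	VV/VV/CC	VL/VV/CC	VL/VV/FC	LL/II/FC	n
Monterrey	1	6	4	0	2	9	1	1	0	0	0	4	0	0	0	28
Guadalupe	5	6	0	1	4	10	1	3	0	0	0	0	0	0	0	30
Poza Rica	0	2	17	0	0	5	2	0	0	0	0	1	2	0	0	29
Minatitlan	17	0	0	1	0	1	0	0	0	1	0	0	0	0	10	30
Cardel	26	1	0	0	1	2	0	0	0	0	0	0	0	0	0	30
Cosoleacaque	4	0	0	0	2	10	0	0	1	0	9	0	0	1	0	27
Villa Hermosa	15	0	0	0	0	14	0	0	0	0	0	1	0	0	0	30
Chiapas	1	4	0	1	2	14	0	1	4	0	1	0	1	0	0	29
Merida	9	0	0	0	1	16	0	1	0	0	0	2	1	0	0	30
San Antonio Kaua	15	0	0	0	1	9	0	3	0	0	0	2	0	0	0	30
Vergel	9	1	0	0	0	19	0	0	0	0	0	1	0	0	0	30
Cancun	3	0	0	0	7	6	6	5	0	0	1	0	0	0	1	29
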