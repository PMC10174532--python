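reporter	label	chromosome	lod	afd	peak_pos	left	right
ODC	IIa	chrII	9.76	0.10	69800	32850	107100
ODC	IIb	chrII	7.13	-0.12	418100	358850	462650
ODC	IVa	chrIV	5.64	-0.10	85150	30400	127400
ODC	V	chrV	12.83	-0.15	291350	247700	325650
ODC	VIIa	chrVII	8.14	-0.15	20000	0	52800
ODC	VIIb	chrVII	28.74	0.23	409000	390050	431700
ODC	X	chrX	16.36	0.18	666850	649350	691550
ODC	XII	chrXII	8.13	0.11	768150	666200	846700
ODC	XIIIa	chrXIII	18.96	0.19	47800	25200	75850
ODC	XIIIb	chrXIII	7.96	0.13	410900	377350	450100
ODC	XIVa	chrXIV	8.81	-0.11	441750	381400	501600
Rpn4	IVb	chrIV	12.64	-0.13	240600	213200	309150
Rpn4	V	chrV	10.09	-0.13	259650	218250	294900
Rpn4	VIIa	chrVII	10.21	-0.15	88550	53550	141350
Rpn4	VIIc	chrVII	6.80	-0.11	882500	840650	926150
Rpn4	XII	chrXII	40.11	0.23	672850	661800	685750
Rpn4	XIVb	chrXIV	16.58	0.15	544150	497300	574600
Rpn4	XV	chrXV	30.00	-0.22	167400	142600	186200
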