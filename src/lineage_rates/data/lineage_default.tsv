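cell	parent	stage	founder	volume_fraction	birth_time_min	cycle_min
P0	-	1-cell	P	1.0	0.0	0.0
AB	P0	2-cell	AB	0.55	0.0	15.0
P1	P0	2-cell	P	0.45	0.0	17.0
ABa	AB	4-cell	AB	0.275	15.0	15.0
ABp	AB	4-cell	AB	0.275	15.0	15.0
EMS	P1	4-cell	EMS	0.225	17.0	14.0
P2	P1	4-cell	P	0.225	17.0	17.0
ABal	ABa	8-cell	AB	0.1375	30.0	15.0
ABar	ABa	8-cell	AB	0.1375	30.0	15.0
ABpl	ABp	8-cell	AB	0.1375	30.0	15.0
ABpr	ABp	8-cell	AB	0.1375	30.0	15.0
MS	EMS	8-cell	MS	0.1125	31.0	16.0
E	EMS	8-cell	E	0.1125	31.0	21.0
C	P2	8-cell	C	0.1125	34.0	14.0
P3	P2	8-cell	P	0.1125	34.0	22.0
ABala	ABal	16-cell	AB	0.06875	45.0	17.0
ABalp	ABal	16-cell	AB	0.06875	45.0	17.0
ABara	ABar	16-cell	AB	0.06875	45.0	17.0
ABarp	ABar	16-cell	AB	0.06875	45.0	17.0
ABpla	ABpl	16-cell	AB	0.06875	45.0	17.0
ABplp	ABpl	16-cell	AB	0.06875	45.0	17.0
ABpra	ABpr	16-cell	AB	0.06875	45.0	17.0
ABprp	ABpr	16-cell	AB	0.06875	45.0	17.0
MSa	MS	16-cell	MS	0.05625	47.0	18.0
MSp	MS	16-cell	MS	0.05625	47.0	18.0
Ea	E	16-cell	E	0.05625	52.0	35.0
Ep	E	16-cell	E	0.05625	52.0	35.0
Ca	C	16-cell	C	0.05625	48.0	17.0
Cp	C	16-cell	C	0.05625	48.0	17.0
D	P3	16-cell	D	0.05625	56.0	26.0
P4	P3	16-cell	P	0.05625	56.0	40.0
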