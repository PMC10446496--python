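nuclei_count	start_min	end_min
1	0.0	0.0
2	0.0	15.0
3	15.0	17.0
4	17.0	30.0
6	30.0	31.0
7	31.0	34.0
8	34.0	45.0
12	45.0	47.0
13	47.0	48.0
14	48.0	52.0
15	52.0	56.0
16	56.0	62.0
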