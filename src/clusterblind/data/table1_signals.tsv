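# Hyperfine-shifted 1H signals of oxidized [Fe2S2]2+ human mitoNEET,
# 600 MHz, shifts at 283 K and 293 K; linewidths measured at 293 K.
# "proposed" holds the distance/NOE-based assignment where one exists
# (alternatives separated by "|"; empty = unassigned exchangeable HN).
label	T_kelvin	shift_ppm	linewidth_hz	exchangeable	proposed
A	283	53.8	2700	False	A:87:HD2
A	293	54.4	2700	False	A:87:HD2
B	283	46.8	2500	True	A:87:HE2
B	293	47.3	2500	True	A:87:HE2
C	283	43.4	2300	False	A:83:HB3
C	293	43.9	2300	False	A:83:HB3
D	283	34.1	1800	False	A:74:HB2
D	293	34.3	1800	False	A:74:HB2
E	283	25.7	1500	False	A:72:HB3
E	293	25.9	1500	False	A:72:HB3
HN1	283	13.6	150	True
HN1	293	13.5	150	True
HN2	283	12.08	200	True
HN2	293	12.02	200	True
HN3	283	11.39	120	True
HN3	293	11.35	120	True
F	283	10.52	250	False	A:74:HA|A:87:HB2
F	293	10.61	250	False	A:74:HA|A:87:HB2
HN4	283	10.15	70	True	A:38:H
HN4	293	10.15	70	True	A:38:H
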