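item	subscale	c1_count	c1	c2	c3	c4	c5	slope	item_total_r	rating
P1	Positive	6	Yes	Yes	Yes	Yes	Yes	0.495	0.686	Very Good
P2	Positive	5	Yes	Somewhat	Yes	Yes	Yes	0.455	0.670	Very Good
P3	Positive	6	Yes	Yes	Yes	Yes	Yes	0.510	0.760	Very Good
P4	Positive	5	Yes	Yes	Yes	Yes	Yes	0.467	0.617	Very Good
P5	Positive	6	Yes	Somewhat	Somewhat	Yes	Yes	0.495	0.673	Good
P6	Positive	5	Yes	Somewhat	Yes	Yes	Yes	0.410	0.650	Very Good
P7	Positive	5	Yes	No	Somewhat	Yes	No	0.382	0.553	Weak
N1	Negative	6	Yes	Yes	Yes	Yes	Yes	0.447	0.771	Very Good
N2	Negative	6	Yes	Yes	Yes	Yes	Yes	0.447	0.809	Very Good
N3	Negative	6	Yes	Yes	Yes	Yes	Yes	0.401	0.796	Very Good
N4	Negative	6	Yes	Yes	Yes	Yes	Yes	0.447	0.773	Very Good
N5	Negative	6	Yes	No	No	No	Yes	0.401	0.599	Weak
N6	Negative	6	Yes	Yes	Yes	Yes	Yes	0.461	0.796	Very Good
N7	Negative	6	Yes	Yes	Yes	Yes	No	0.372	0.596	Very Good
G1	General	4	No	No	Somewhat	No	No	0.395	0.541	Weak
G2	General	5	Yes	No	Somewhat	No	Yes	0.481	0.565	Weak
G3	General	4	No	No	No	No	No	0.377	0.431	Weak
G4	General	6	Yes	Yes	Yes	Yes	Yes	0.437	0.630	Very Good
G5	General	4	No	Somewhat	No	No	No	0.373	0.463	Weak
G6	General	5	Yes	Yes	Yes	Yes	Yes	0.437	0.600	Very Good
G7	General	5	Yes	Yes	Yes	No	No	0.382	0.606	Good
G8	General	5	Yes	Yes	Yes	Yes	Yes	0.431	0.617	Very Good
G9	General	6	Yes	Yes	Yes	Yes	Yes	0.437	0.605	Very Good
G10	General	4	No	Somewhat	No	Yes	No	0.382	0.441	Weak
G11	General	4	No	No	Somewhat	No	No	0.377	0.567	Weak
G12	General	4	No	No	No	Yes	No	0.350	0.381	Weak
G13	General	5	Yes	Yes	Yes	Yes	Yes	0.426	0.601	Very Good
G14	General	6	Yes	Yes	Somewhat	Yes	Yes	0.442	0.604	Very Good
G15	General	4	No	No	No	Yes	No	0.377	0.438	Weak
G16	General	4	No	No	No	No	No	0.377	0.366	Weak
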