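form	subscale	lambda1	lambda2	ratio	unidimensional
full	Positive	3.172	0.949	3.342	Yes
full	Negative	3.867	0.925	4.181	Yes
full	General	4.080	2.130	1.915	No
short	Positive	2.920	0.798	3.659	Yes
short	Negative	3.628	0.784	4.628	Yes
short	General	3.332	1.109	3.005	Yes
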