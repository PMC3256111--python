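subscale	short_score	full_score
Positive	6	7
Positive	7	8
Positive	8	9
Positive	9	10
Positive	10	11
Positive	11	13
Positive	12	14
Positive	13	15
Positive	14	16
Positive	15	17
Positive	16	18
Positive	17	20
Positive	18	21
Positive	19	22
Positive	20	23
Positive	21	24
Positive	22	25
Positive	23	26
Positive	24	28
Positive	25	29
Positive	26	30
Positive	27	32
Positive	28	33
Positive	29	34
Positive	30	35
Positive	31	37
Negative	6	7
Negative	7	8
Negative	8	9
Negative	9	10
Negative	10	12
Negative	11	13
Negative	12	14
Negative	13	15
Negative	14	16
Negative	15	18
Negative	16	19
Negative	17	20
Negative	18	21
Negative	19	22
Negative	20	24
Negative	21	25
Negative	22	26
Negative	23	27
Negative	24	28
Negative	25	29
Negative	26	30
Negative	27	32
Negative	28	33
Negative	29	34
Negative	30	35
Negative	31	36
Negative	32	37
Negative	33	38
Negative	34	39
Negative	35	40
Negative	36	42
Negative	37	43
General	7	19
General	8	23
General	9	25
General	10	27
General	11	29
General	12	30
General	13	33
General	14	34
General	15	36
General	16	38
General	17	40
General	18	41
General	19	43
General	20	45
General	21	47
General	22	49
General	23	51
General	24	52
General	25	54
General	26	56
General	27	58
General	28	60
General	29	62
General	30	64
General	31	66
General	32	67
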