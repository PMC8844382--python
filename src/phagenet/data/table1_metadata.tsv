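dataset	n_hosts	n_phages	matrix_size
Hong et al. (2013)	7	3	21
Shende et al. (2017)	8	5	40
Mizuno et al. (2020)	32	2	64
Liao et al. (2019)	17	4	68
Krasowska et al. (2015)	19	4	76
VHR1, James L. Van Etten lab	6	13	78
Gutiérrez et al. (2015)	45	2	90
Hwang et al. (2009)	16	6	96
Kwiatek et al. (2015)	20	5	100
Hammerl et al. (2016)	36	3	108
Xie et al. (2016)	12	10	120
Magaré et al. (2017)	5	25	125
Álvarez et al. (2019)	42	3	126
Pereira et al. (2016)	42	3	126
Yu et al. (2016)	31	5	155
VHR5	12	13	156
Denou et al. (2009)	26	6	156
Schouler et al. (2021)	56	3	168
Gutierrez et al. (2010)	65	3	195
Dias et al. (2013)	20	10	200
Maura et al. (2012)	73	3	219
Galtier et al. (2017)	73	3	219
Alič et al. (2017)	55	4	220
Molina et al. (2021) (3C)	26	10	260
Salifu et al. (2013)	27	10	270
Arachchi et al. (2014)	50	6	300
Oh et al. (2017)	27	12	324
Wandro et al. (2019)	15	22	330
Gunathilaka et al. (2017)	12	29	348
Jurczak-Kurek et al. (2016)	60	6	360
Litt and Jaroni (2017)	54	7	378
Romero-Suarez et al. (2012)	16	26	416
Wang et al. (2015)	41	11	451
Murphy et al. (2013)	20	24	480
Sajben-Nagy et al. (2012)	34	16	544
Sekulovic et al. (2014)	37	15	555
Mangieri et al. (2020)	30	21	630
Galtier et al. (2016)	73	12	876
Vu et al. (2019)	31	39	1209
VHR14, Mathieu et al. (2020)	84	16	1344
Molina et al. (2021) (3A)	56	26	1456
Petsong et al. (2019)	47	36	1692
Jäckel et al. (2017)	113	19	2147
Brady et al. (2017)	40	57	2280
Lourenço et al. (2020)	98	28	2744
Fong et al. (2019)	61	46	2806
Gencay et al. (2019)	72	41	2952
Korf et al. (2019)	64	50	3200
Saussereau et al. (2014)	896	10	8960
Mathieu et al. (2020)	75	166	12450
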