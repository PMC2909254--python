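parameter	mean1	sd1	n1	mean2	sd2	n2	units
Al	12.3	5.4	4	28.8	0.7	4	ppm
B	1.1	0.1	4	0.3	0.0	4	ppm
C	10.7	1.6	4	1.6	0.2	4	%
Ca_BS	15.9	2.0	4	42.9	3.3	4	%BS
Ca	1014.3	89.5	4	1349.8	83.4	4	ppm
Ca_Mg	0.4	0.0	4	2.0	0.0	4	ratio
CEC	32.3	2.1	4	16.6	0.9	4	meq/100g
Cd	0.38	0.1	4	0	0.0	4	ppm
Cr	0.5	0.1	4	0.2	0.1	4	ppm
Cu	0.1	0.1	4	0.4	0.1	4	ppm
Fe	23.3	4.8	4	6.9	0.8	4	ppm
K_BS	0.7	0.2	4	2.6	0.40	4	%BS
K	81.3	21.7	4	154.5	26.2	4	ppm
Mg_BS	60.4	5.7	4	22.4	8.6	4	%BS
Mg	2378.8	327.6	4	430.5	171.8	4	ppm
Mn	180.6	44.0	4	117.8	7.1	4	ppm
N	0.5	0.1	4	0.2	0.0	4	%
Ni	29.8	8.1	4	1.0	0.4	4	ppm
NO3_N	7.8	3.3	4	1.3	0.0	4	ppm
P	27.3	3.9	4	7.5	2.1	4	ppm
Pb	31.7	0.3	4	30.5	0.0	4	ppm
pH	6.1	0.1	4	5.3	0.1	4	pH
Zn	1.9	0.9	4	1.1	0.5	4	ppm
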