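species_label	mz_printed	rt_standard_min	rt_retina_min	role
21:5 (IS)	315.233		3.19	internal_standard
20:4	303.233		3.3	other
20:5	301.2173		3.11	other
22:4	331.2643		3.58	other
22:5 (1)	329.2486		3.35	other
22:5 (2)	329.2486		3.44	other
22:6	327.233	3.24	3.23	other
24:4 (1)	359.2956		3.91	other
24:4 (2)			4.02	other
24:5	357.2799	3.66	3.69	other
24:6	355.2643		3.45	other
26:4	387.3269		4.32	other
26:5	385.3112		4.03	other
26:6	383.2956		3.73	other
28:4	415.3582		4.76	other
28:5	413.3425		4.42	other
28:6	411.3269		4.12	other
30:4	443.3895		5.26	other
30:5 (1)	441.3738		4.89	other
30:5 (2)	441.3738		4.99	other
30:6	439.3582		ND	other
32:4 (1)	471.4208		5.76	other
32:4 (2)	471.4208		5.91	other
32:5 (1)	469.4051		5.34	other
32:5 (2)	469.4051		5.45	other
32:6	467.3895	4.98	5.01	marker
34:4	499.4521		6.28	marker
34:5	497.4364	5.88	5.89	marker
34:6	495.4208	5.42	5.46	marker
36:4	527.4834		6.67	other
36:5	525.4677		6.34	other
36:6	523.4521		5.94	marker
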