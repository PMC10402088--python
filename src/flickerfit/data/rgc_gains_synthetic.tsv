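cell_class	channel	ecc_deg	freq_hz	gain
midget	achromatic	5.0	1.0	0.0834
midget	achromatic	5.0	2.0	0.1292
midget	achromatic	5.0	4.0	0.2223
midget	achromatic	5.0	8.0	0.3363
midget	achromatic	5.0	16.0	0.2821
midget	achromatic	5.0	32.0	0.067
midget	achromatic	5.0	64.0	0.0027
midget	achromatic	25.0	1.0	0.1098
midget	achromatic	25.0	2.0	0.1614
midget	achromatic	25.0	4.0	0.2752
midget	achromatic	25.0	8.0	0.4445
midget	achromatic	25.0	16.0	0.4653
midget	achromatic	25.0	32.0	0.1634
midget	achromatic	25.0	64.0	0.011
midget	achromatic	40.0	1.0	0.1253
midget	achromatic	40.0	2.0	0.1765
midget	achromatic	40.0	4.0	0.2958
midget	achromatic	40.0	8.0	0.4937
midget	achromatic	40.0	16.0	0.59
midget	achromatic	40.0	32.0	0.2714
midget	achromatic	40.0	64.0	0.0264
midget	chromatic	5.0	1.0	0.3521
midget	chromatic	5.0	2.0	0.5999
midget	chromatic	5.0	4.0	0.8001
midget	chromatic	5.0	8.0	0.4748
midget	chromatic	5.0	16.0	0.0663
midget	chromatic	5.0	32.0	0.0014
midget	chromatic	5.0	64.0	0.0
midget	chromatic	25.0	1.0	0.2249
midget	chromatic	25.0	2.0	0.3872
midget	chromatic	25.0	4.0	0.5802
midget	chromatic	25.0	8.0	0.4733
midget	chromatic	25.0	16.0	0.1074
midget	chromatic	25.0	32.0	0.0041
midget	chromatic	25.0	64.0	0.0
midget	chromatic	40.0	1.0	0.1874
midget	chromatic	40.0	2.0	0.3227
midget	chromatic	40.0	4.0	0.4835
midget	chromatic	40.0	8.0	0.3944
midget	chromatic	40.0	16.0	0.0895
midget	chromatic	40.0	32.0	0.0034
midget	chromatic	40.0	64.0	0.0
parasol	achromatic	5.0	1.0	0.4178
parasol	achromatic	5.0	2.0	0.5882
parasol	achromatic	5.0	4.0	0.9861
parasol	achromatic	5.0	8.0	1.6455
parasol	achromatic	5.0	16.0	1.9665
parasol	achromatic	5.0	32.0	0.9046
parasol	achromatic	5.0	64.0	0.088
parasol	achromatic	25.0	1.0	0.5058
parasol	achromatic	25.0	2.0	0.6577
parasol	achromatic	25.0	4.0	1.0496
parasol	achromatic	25.0	8.0	1.8032
parasol	achromatic	25.0	16.0	2.5735
parasol	achromatic	25.0	32.0	1.8238
parasol	achromatic	25.0	64.0	0.3318
parasol	achromatic	40.0	1.0	0.5601
parasol	achromatic	40.0	2.0	0.6856
parasol	achromatic	40.0	4.0	1.036
parasol	achromatic	40.0	8.0	1.7783
parasol	achromatic	40.0	16.0	2.787
parasol	achromatic	40.0	32.0	2.6214
parasol	achromatic	40.0	64.0	0.7567
bistratified	S	5.0	1.0	0.1638
bistratified	S	5.0	2.0	0.2797
bistratified	S	5.0	4.0	0.4491
bistratified	S	5.0	8.0	0.4598
bistratified	S	5.0	16.0	0.1548
bistratified	S	5.0	32.0	0.0098
bistratified	S	5.0	64.0	0.0001
bistratified	S	25.0	1.0	0.1617
bistratified	S	25.0	2.0	0.2646
bistratified	S	25.0	4.0	0.4507
bistratified	S	25.0	8.0	0.6001
bistratified	S	25.0	16.0	0.3547
bistratified	S	25.0	32.0	0.0493
bistratified	S	25.0	64.0	0.001
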