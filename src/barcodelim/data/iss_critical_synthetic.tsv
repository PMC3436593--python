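n_otu	length	topology	iss_c
4	200	sym	0.5263
4	400	sym	0.5209
4	800	sym	0.5247
4	1600	sym	0.5264
4	3200	sym	0.5326
4	200	asym	0.3972
4	400	asym	0.4569
4	800	asym	0.5061
4	1600	asym	0.5103
4	3200	asym	0.5195
8	200	sym	0.5924
8	400	sym	0.6441
8	800	sym	0.6455
8	1600	sym	0.6446
8	3200	sym	0.6458
8	200	asym	0.4613
8	400	asym	0.4412
8	800	asym	0.5697
8	1600	asym	0.6139
8	3200	asym	0.6177
16	200	sym	0.5655
16	400	sym	0.7289
16	800	sym	0.7267
16	1600	sym	0.7265
16	3200	sym	0.7265
16	200	asym	0.5236
16	400	asym	0.5521
16	800	asym	0.4724
16	1600	asym	0.6742
16	3200	asym	0.6753
32	200	sym	0.5790
32	400	sym	0.7776
32	800	sym	0.7785
32	1600	sym	0.7789
32	3200	sym	0.7779
32	200	asym	0.5344
32	400	asym	0.5743
32	800	asym	0.5331
32	1600	asym	0.5514
32	3200	asym	0.5629
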