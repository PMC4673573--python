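# chain: G3G3G3G3G
# seed: 17
# label: laminaripentaose_synthetic
# precursor_mz: 1089.5305
211.1644	0.0593
227.0916	1.0000
241.1215	0.0926
259.1331	0.0741
315.3446	0.0400
338.8854	0.0281
366.4730	0.0052
386.2620	0.0004
401.1175	0.0586
428.4102	0.0232
445.0789	0.0664
463.3080	0.0699
480.3898	0.0341
519.0336	0.0891
544.5205	0.0393
605.2575	0.0856
614.7512	0.0523
628.9805	0.0014
643.5331	0.0143
649.2097	0.0504
667.5013	0.0993
723.3980	0.0988
764.1787	0.0524
853.3173	0.0704
871.1715	0.0653
927.4178	0.0425
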