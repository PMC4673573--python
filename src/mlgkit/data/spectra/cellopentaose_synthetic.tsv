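# chain: G4G4G4G4G
# seed: 41
# label: cellopentaose_synthetic
# precursor_mz: 1089.5305
211.0193	0.9158
227.1679	0.0774
241.0466	0.0446
241.7085	0.0499
259.0354	0.0774
271.1659	0.0334
277.2877	0.0207
315.2890	0.0674
329.1843	1.0000
401.1853	0.8746
431.1671	0.0719
445.2544	0.0701
463.1725	0.0674
519.2554	0.0547
533.3075	0.5762
605.1254	0.6766
635.2705	0.0345
649.2620	0.0751
667.1628	0.0771
701.0663	0.0036
710.2772	0.0240
723.3501	0.0284
737.4679	0.9462
763.1712	0.0487
809.5308	0.6398
811.1129	0.0337
826.2250	0.0087
839.4330	0.0744
853.4898	0.0587
866.2555	0.0494
871.4520	0.0683
927.4986	0.0432
941.3399	0.7734
973.1269	0.0263
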