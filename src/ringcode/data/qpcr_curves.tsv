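gene	efficiency	intercept	role
Or67d	1.004581	30.0	or_panel
Or23a	1.022281	30.0	or_panel
Or2a	1.05291	30.0	or_panel
Or47b	1.012215	30.0	or_panel
Gr21a	0.9796537	30.0	or_panel
Or92a	0.9533596	30.0	or_panel
Or85a	0.9776528	30.0	or_panel
Or22a	1.034769	30.0	or_panel
Or56a	0.9354389	30.0	or_panel
Or82a	0.943322	30.0	or_panel
Or49b	1.008808	30.0	or_panel
Or98a	0.956284	30.0	or_panel
Or9a	0.9326372	30.0	or_panel
Or67b	1.068821	30.0	or_panel
Or67a	1.045276	30.0	or_panel
IR31a	0.9775197	30.0	or_panel
IR41a	1.020108	30.0	or_panel
Or35a	0.9652927	30.0	or_panel
IR84a	0.9322729	30.0	or_panel
Or13a	0.9915544	30.0	or_panel
ACT5C	1.029591	25.0	reference
GAPDH2	1.053987	25.0	reference
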