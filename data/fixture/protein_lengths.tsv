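G0000	542
G0003	260
G0004	458
G0006	284
G0007	117
G0008	565
G0017	249
G0018	973
G0019	898
G0020	656
G0022	885
G0024	767
G0025	162
G0026	181
G0029	393
G0035	947
G0036	721
G0042	982
G0043	934
G0044	570
G0045	310
G0046	696
G0053	572
G0054	771
G0055	104
G0056	389
G0057	449
G0058	599
G0062	525
G0063	230
G0068	115
G0069	568
G0070	369
G0073	455
G0075	337
G0076	892
G0079	590
G0085	742
G0088	895
G0090	931
G0092	360
G0097	177
G0100	703
G0101	185
G0105	111
G0106	449
G0107	871
G0113	315
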