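G0000	gene
G0001	gene
G0002	gene
G0003	gene
G0004	gene
G0005	gene
G0006	gene
G0007	gene
G0008	gene
G0009	gene
G0010	gene
G0011	gene
G0012	gene
G0013	gene
G0014	gene
G0015	gene
G0016	gene
G0017	gene
G0018	gene
G0019	gene
G0020	gene
G0021	gene
G0022	gene
G0023	gene
G0024	gene
G0025	gene
G0026	gene
G0027	gene
G0028	gene
G0029	gene
G0030	gene
G0031	gene
G0032	gene
G0033	gene
G0034	gene
G0035	gene
G0036	gene
G0037	gene
G0038	gene
G0039	gene
G0040	gene
G0041	gene
G0042	gene
G0043	gene
G0044	gene
G0045	gene
G0046	gene
G0047	gene
G0048	gene
G0049	gene
G0050	gene
G0051	gene
G0052	gene
G0053	gene
G0054	gene
G0055	gene
G0056	gene
G0057	gene
G0058	gene
G0059	gene
G0060	gene
G0061	gene
G0062	gene
G0063	gene
G0064	gene
G0065	gene
G0066	gene
G0067	gene
G0068	gene
G0069	gene
G0070	gene
G0071	gene
G0072	gene
G0073	gene
G0074	gene
G0075	gene
G0076	gene
G0077	gene
G0078	gene
G0079	gene
G0080	gene
G0081	gene
G0082	gene
G0083	gene
G0084	gene
G0085	gene
G0086	gene
G0087	gene
G0088	gene
G0089	gene
G0090	gene
G0091	gene
G0092	gene
G0093	gene
G0094	gene
G0095	gene
G0096	gene
G0097	gene
G0098	gene
G0099	gene
G0100	gene
G0101	gene
G0102	gene
G0103	gene
G0104	gene
G0105	gene
G0106	gene
G0107	gene
G0108	gene
G0109	gene
G0110	gene
G0111	gene
G0112	gene
G0113	gene
G0114	gene
G0115	gene
G0116	gene
G0117	gene
G0118	gene
G0119	gene
M000	metabolite
M001	metabolite
M002	metabolite
M003	metabolite
M004	metabolite
M005	metabolite
M006	metabolite
M007	metabolite
M008	metabolite
M009	metabolite
M010	metabolite
M011	metabolite
M012	metabolite
M013	metabolite
M014	metabolite
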