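module_1	planted perturbed module	G0008	G0029	G0055	G0082	G0084	G0089	G0105	M009
module_2	planted perturbed module	G0004	G0011	G0030	G0033	G0046	G0058	G0085	G0092
decoy_01	random decoy set	G0010	G0016	G0041	G0075	G0082	G0094	G0103	G0118	M007	M009	M010
decoy_02	random decoy set	G0000	G0007	G0076	G0085	G0086	G0088	G0097	G0104	M008	M012	M014
decoy_03	random decoy set	G0023	G0030	G0050	G0052	G0063	G0065	G0103	G0114	M002	M004	M011
decoy_04	random decoy set	G0013	G0087	G0091	G0094	G0098	G0105	G0112	G0115	M001	M002	M012
decoy_05	random decoy set	G0015	G0019	G0021	G0032	G0092	G0098	G0101	G0115	M008	M010	M011
decoy_06	random decoy set	G0005	G0010	G0027	G0049	G0068	G0083	G0084	G0096	M002	M005	M014
decoy_07	random decoy set	G0053	G0054	G0067	G0085	G0096	G0106	G0107	G0117	M008	M010	M014
decoy_08	random decoy set	G0000	G0006	G0017	G0041	G0042	G0095	G0107	G0108	M005	M008	M013
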