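G0000	G0001	0.5642851014
G0000	G0002	0.8007491788
G0000	G0003	0.5352102881
G0000	G0005	0.8314214763
G0000	G0006	0.8940197973
G0000	G0009	0.795797652
G0000	G0011	0.6385724463
G0000	G0015	0.7344540817
G0000	G0018	0.5273340307
G0000	G0021	0.9195624242
G0000	G0024	0.5950850084
G0000	G0028	0.6703430879
G0000	G0034	0.7215654706
G0000	G0039	0.5393348793
G0000	G0060	0.6700411822
G0000	G0068	0.7141863013
G0000	G0083	0.6825527142
G0000	G0093	0.5798573203
G0000	G0103	0.5056659393
G0000	G0117	0.7566731401
G0001	G0002	0.5143445042
G0001	G0008	0.7768651814
G0001	G0021	0.7331515986
G0001	G0023	0.7991960537
G0001	G0026	0.9264599972
G0001	G0047	0.732471863
G0001	G0051	0.6429110738
G0001	G0060	0.8749222165
G0001	G0072	0.5337826484
G0001	G0080	0.6097311258
G0001	G0087	0.7240124925
G0001	G0095	0.6994794628
G0001	G0109	0.7890151239
G0002	G0003	0.5648869747
G0002	G0004	0.8109417964
G0002	G0005	0.6376544079
G0002	G0006	0.8351802921
G0002	G0007	0.908368218
G0002	G0012	0.714974346
G0002	G0017	0.9982179378
G0002	G0022	0.869623437
G0002	G0023	0.9478788759
G0002	G0031	0.8709035482
G0002	G0034	0.8931423943
G0002	G0041	0.8184903055
G0002	G0044	0.5430819453
G0002	G0045	0.9536275631
G0002	G0064	0.7775343571
G0002	G0083	0.9436863296
G0002	G0095	0.5635900677
G0002	G0098	0.8998463248
G0002	G0101	0.7332396764
G0002	G0106	0.6131198292
G0002	G0111	0.7771084431
G0002	G0116	0.7060625471
G0003	G0004	0.6844965619
G0003	G0007	0.7745376344
G0003	G0015	0.9530671694
G0003	G0017	0.7298579899
G0003	G0020	0.5446186272
G0003	G0032	0.8461395533
G0003	G0036	0.5815284162
G0003	G0039	0.8054898937
G0003	G0046	0.9032007121
G0003	G0073	0.9954647567
G0003	G0088	0.9351849602
G0003	G0101	0.8589281001
G0004	G0010	0.9336667759
G0004	G0019	0.7939409703
G0004	G0030	0.7020187937
G0004	G0074	0.7092696875
G0004	G0097	0.9500138737
G0004	G0109	0.5010788891
G0005	G0081	0.8049571572
G0005	G0100	0.8994112355
G0006	G0010	0.5643798356
G0006	G0022	0.597826415
G0006	G0030	0.6225470256
G0006	G0037	0.6786098564
G0006	G0038	0.8181807109
G0006	G0040	0.5193194664
G0006	G0057	0.5143502361
G0006	G0071	0.9310527452
G0006	G0073	0.7680265411
G0006	G0075	0.7707568452
G0006	G0086	0.831676579
G0006	G0090	0.6458575064
G0007	G0008	0.7418123485
G0007	G0027	0.6290704259
G0007	G0054	0.7075552404
G0007	G0090	0.8603282697
G0008	G0009	0.6176506158
G0008	G0011	0.5415584989
G0008	G0013	0.6011080139
G0008	G0061	0.5766216794
G0008	G0063	0.7239366982
G0008	G0082	0.7260148631
G0008	G0087	0.5586923996
G0008	G0092	0.9838139512
G0009	G0014	0.5165373437
G0009	G0027	0.9891505687
G0009	G0028	0.7180007518
G0009	G0029	0.8732544587
G0009	G0115	0.9587340073
G0009	G0119	0.8611368868
G0010	G0016	0.6696603304
G0010	G0024	0.5464507108
G0010	G0035	0.8796140771
G0010	G0043	0.6976341131
G0010	G0051	0.8028914523
G0010	G0061	0.9382283041
G0010	G0062	0.8723393696
G0010	G0069	0.8084674047
G0010	G0117	0.8804960563
G0011	G0012	0.57384565
G0011	G0013	0.9507155393
G0011	G0016	0.5084386075
G0011	G0019	0.6543548716
G0011	G0033	0.5748675869
G0011	G0097	0.9558092512
G0011	M011	0.710608328
G0012	G0018	0.5170251395
G0012	G0091	0.8457932398
G0013	G0014	0.6003844771
G0013	G0036	0.9994012438
G0013	G0050	0.568947739
G0014	G0043	0.9563194174
G0014	G0045	0.8501220289
G0014	G0054	0.7766201172
G0014	G0062	0.7797989573
G0014	G0065	0.9015760977
G0014	G0102	0.6820666436
G0014	G0107	0.6873715365
G0014	G0110	0.6586184438
G0015	G0040	0.5576187518
G0015	M012	0.788187694
G0016	G0053	0.8673447993
G0016	G0114	0.8729531912
G0017	G0025	0.6464875335
G0017	G0026	0.6086056518
G0017	G0031	0.7728969913
G0017	G0035	0.517704102
G0017	G0048	0.8593171086
G0017	G0052	0.6199088291
G0017	G0056	0.5480277034
G0017	G0079	0.7538573969
G0017	G0085	0.5767885061
G0017	G0089	0.8367017771
G0017	G0091	0.7510796046
G0018	G0020	0.5863348006
G0018	G0025	0.863555872
G0018	G0050	0.6951950168
G0019	G0053	0.6452089758
G0019	G0059	0.8777617017
G0019	G0064	0.9073018
G0020	G0070	0.7497046903
G0020	G0077	0.7027556167
G0021	G0032	0.8905274117
G0021	G0042	0.67603305
G0021	G0086	0.9045999531
G0021	G0113	0.7210211092
G0021	G0116	0.8438215079
G0021	M011	0.9481394622
G0022	G0029	0.5200065513
G0022	M007	0.9547351648
G0023	G0047	0.5246613277
G0023	G0076	0.9334884365
G0024	G0038	0.57987412
G0024	G0046	0.8416873687
G0024	G0065	0.7480495598
G0025	G0044	0.7807510135
G0025	G0067	0.5454812659
G0027	G0042	0.5653295034
G0028	G0066	0.5541511691
G0029	G0055	0.7591886878
G0029	G0080	0.6929797621
G0029	G0082	0.9374253267
G0029	G0084	0.7033070069
G0029	G0089	0.686639739
G0029	G0118	0.839150109
G0029	M009	0.9414516356
G0030	G0033	0.8130650789
G0030	G0092	0.5830452583
G0031	G0052	0.8112837439
G0031	G0057	0.577456543
G0031	G0068	0.9260145206
G0031	G0069	0.7068750742
G0031	M013	0.9680465725
G0033	G0058	0.891907191
G0033	G0085	0.7875989776
G0034	G0041	0.6624003236
G0034	G0078	0.5397963158
G0035	G0037	0.5304433515
G0035	M010	0.5894987033
G0036	G0078	0.5795418082
G0037	G0049	0.6336287885
G0037	G0055	0.6288090827
G0037	G0070	0.5670645376
G0038	G0048	0.90231405
G0038	G0059	0.6493922335
G0038	M010	0.8068969561
G0040	G0049	0.8948702572
G0040	G0103	0.7962115074
G0040	M005	0.6541040535
G0040	M013	0.923647417
G0042	G0093	0.9687284857
G0043	G0110	0.6936956334
G0044	G0119	0.84153413
G0044	M001	0.6236336453
G0045	M006	0.5126164699
G0046	G0058	0.8184831986
G0046	G0066	0.9378502649
G0046	G0094	0.6659830078
G0046	M014	0.9634161345
G0049	G0063	0.7828965203
G0051	G0098	0.7388078901
G0052	G0099	0.69865753
G0052	G0118	0.5243643292
G0053	G0102	0.8292635446
G0054	G0056	0.6624618381
G0054	G0067	0.8096665092
G0054	G0076	0.883121012
G0054	G0111	0.8120838573
G0055	G0077	0.8687364532
G0055	G0104	0.9329102524
G0055	G0105	0.5089629259
G0056	M002	0.905345424
G0057	G0096	0.6956513
G0057	G0100	0.6230101537
G0060	G0071	0.5856171226
G0060	M008	0.6354491725
G0061	G0108	0.9437976492
G0062	G0081	0.5146020477
G0063	G0107	0.668568466
G0064	G0072	0.7298978516
G0064	G0075	0.6439799761
G0066	G0094	0.5841601466
G0066	G0108	0.6828387847
G0068	G0074	0.6036800352
G0070	M000	0.6472788373
G0072	M014	0.6973109546
G0074	G0104	0.7079351007
G0074	G0113	0.607523857
G0076	G0079	0.5357043735
G0076	G0084	0.8730365809
G0076	G0112	0.9787268393
G0077	M004	0.6530357075
G0077	M011	0.8899000416
G0080	G0088	0.983805109
G0081	G0096	0.7915842132
G0082	G0105	0.513638925
G0085	G0106	0.5336327384
G0085	G0112	0.6773713111
G0092	G0099	0.6997718962
G0094	G0115	0.5640239564
G0097	M010	0.8960729878
G0099	M001	0.5156056741
G0101	G0114	0.9713944488
G0103	M012	0.6925724953
G0112	M006	0.6945354937
G0115	M003	0.9869850206
G0115	M012	0.8409346116
G0119	M013	0.8544848783
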