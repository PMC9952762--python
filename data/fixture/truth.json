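{
 "parameters": {
  "attach_m": 2,
  "k_modules": 2,
  "module_size": 8,
  "n_genes": 120,
  "n_metabolites": 15,
  "n_reps": 3,
  "noise_sd": 0.3,
  "signal_mean": 2.0,
  "signal_sd": 0.4
 },
 "planted_modules": [
  [
   "G0008",
   "G0029",
   "G0055",
   "G0082",
   "G0084",
   "G0089",
   "G0105",
   "M009"
  ],
  [
   "G0004",
   "G0011",
   "G0030",
   "G0033",
   "G0046",
   "G0058",
   "G0085",
   "G0092"
  ]
 ],
 "seed": 11,
 "true_log2fc": {
  "G0000": 0.18385868228402805,
  "G0001": 0.1973670486163501,
  "G0002": -0.10332079992616895,
  "G0003": -0.14921161064875663,
  "G0004": 2.1983520265856886,
  "G0005": -0.03443183502206097,
  "G0006": -0.18163560280513041,
  "G0007": -0.17830182525145613,
  "G0008": -2.296635368515393,
  "G0009": -0.08501261268118734,
  "G0010": -0.2185253181550358,
  "G0011": 1.235692534329341,
  "G0012": 0.22989833578362015,
  "G0013": -0.4788259001386301,
  "G0014": 0.24706863858470757,
  "G0015": -0.1876699410775352,
  "G0016": -0.16378198670823324,
  "G0017": -0.40525414255973696,
  "G0018": -0.043272635654691034,
  "G0019": -0.07429845278021022,
  "G0020": 0.057436749161416924,
  "G0021": -0.16013228877748034,
  "G0022": 0.028126853791039973,
  "G0023": 0.545907551438728,
  "G0024": 0.1226999083360786,
  "G0025": -0.17210701114671553,
  "G0026": 0.28593287857160143,
  "G0027": -0.038640340190747455,
  "G0028": 0.17816234042937143,
  "G0029": -2.289582616659996,
  "G0030": 2.058825666351331,
  "G0031": 0.183824228684309,
  "G0032": -0.1173197150282767,
  "G0033": 1.6372226994962815,
  "G0034": -0.5790862492577954,
  "G0035": -0.10429608697648253,
  "G0036": 0.1654366271398712,
  "G0037": -0.11403312196001836,
  "G0038": 0.13169079446490844,
  "G0039": 0.29386211149799213,
  "G0040": -0.16323402451922606,
  "G0041": 0.3694055257623869,
  "G0042": 0.4865413385064414,
  "G0043": 0.3237137832612244,
  "G0044": 0.3496388521881808,
  "G0045": 0.32903893433293346,
  "G0046": 2.7101557548984565,
  "G0047": 0.6763617181713454,
  "G0048": 0.0557582713922821,
  "G0049": 0.0006252248553804646,
  "G0050": 0.18093219155706547,
  "G0051": -0.2724585355931749,
  "G0052": -0.46595302946536304,
  "G0053": -0.26460239178801886,
  "G0054": 0.11176960504279282,
  "G0055": -2.6475104893336305,
  "G0056": 0.1419160022244914,
  "G0057": -0.46090761548752285,
  "G0058": 2.354739630583517,
  "G0059": -0.5650391125625511,
  "G0060": -0.09484267287317595,
  "G0061": -0.056416954822469244,
  "G0062": -0.01476024990012849,
  "G0063": 0.20140873399111048,
  "G0064": 0.3686502534657764,
  "G0065": 0.06926892897232247,
  "G0066": 0.18380541108112097,
  "G0067": -0.32856050784220153,
  "G0068": -0.3528924043390715,
  "G0069": 0.070871500348712,
  "G0070": 0.19939893083517982,
  "G0071": 0.21787303677362632,
  "G0072": 0.17782259733119873,
  "G0073": 0.23525211269288315,
  "G0074": 0.2429484089989888,
  "G0075": -0.5256556091812962,
  "G0076": -0.22024973068515816,
  "G0077": 0.13654792269190166,
  "G0078": 0.17900158952009698,
  "G0079": -0.4536277228499349,
  "G0080": 0.35191840996859586,
  "G0081": -0.1316495771539457,
  "G0082": -1.5177767429414684,
  "G0083": -0.06972742481312455,
  "G0084": -1.7492178115694506,
  "G0085": 2.3797397933032136,
  "G0086": 0.08214559342810773,
  "G0087": 0.2248905696145327,
  "G0088": -0.4299350980174779,
  "G0089": -1.4717347153579499,
  "G0090": 0.2969737730922429,
  "G0091": 0.0231880403163418,
  "G0092": 1.9768580149996122,
  "G0093": -0.23124404847645286,
  "G0094": -0.0825819424582913,
  "G0095": -0.6557515045795858,
  "G0096": -0.19428555738062564,
  "G0097": 0.05457289530645562,
  "G0098": -0.21271514256578355,
  "G0099": -0.09840385847949942,
  "G0100": -0.044028710256709645,
  "G0101": 0.014514267776158912,
  "G0102": 0.30619099960566526,
  "G0103": -0.007468733974519141,
  "G0104": -0.07799038077173116,
  "G0105": -1.956898996820788,
  "G0106": 0.1615935668174315,
  "G0107": 0.62298511815322,
  "G0108": -0.10282430266658295,
  "G0109": 0.15386017581702224,
  "G0110": -0.47319148500341,
  "G0111": 0.40364816111407736,
  "G0112": 0.19781505171280875,
  "G0113": 0.3998399004024063,
  "G0114": -0.01771807691356559,
  "G0115": -0.312844669203667,
  "G0116": 0.26582967363795135,
  "G0117": 0.22606005244737912,
  "G0118": -0.2601116692949822,
  "G0119": -0.4418805323838502,
  "M000": 0.1347396341367471,
  "M001": -0.051417598225643533,
  "M002": 0.783649767065762,
  "M003": -0.18427393572780917,
  "M004": -0.15856868207754454,
  "M005": -0.03322927855468393,
  "M006": -0.4995171741460338,
  "M007": -0.26672610868139607,
  "M008": 0.49330881027167506,
  "M009": -2.3995054621268093,
  "M010": -0.03941322677102743,
  "M011": -0.18251657332004037,
  "M012": -0.3815693975621846,
  "M013": 0.17414493834492273,
  "M014": 0.19748929418050534
 }
}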