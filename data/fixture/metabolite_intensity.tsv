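feature_id	WT_1	WT_2	WT_3	KO_1	KO_2	KO_3
M000	33040.2575349014	12067.1588760886	20973.7951454202	25922.3644017405	22380.1855227796	17546.6857661957
M001	80742.8908043385	83416.7546643257	137551.857515326	112514.298560369	90605.5736144242	125684.415097918
M002	35127.4391481809	21604.5993741986	26852.0631777105	43340.2230062978	50297.5260709556	46063.6822561283
M003	70208.5458895501	33612.0542412323	48232.7497688404	54211.1294022167	26598.2953091395	51583.7087737135
M004	4594.05355604821	9198.10764303031	10955.5493774059	5222.88479600868	10940.8642687172	5021.478945048
M005	17306.0116453538	11720.6777781171	10896.8805281875	7720.22508805947	7722.6776218736	14406.9391926086
M006	56301.1265516589	120067.926179428	30927.2511291936	39290.7371962547	49495.9398405567	38043.0319708102
M007	79164.4162011974	35466.1019430495	52863.3607136624	41864.8889396488	74183.0362270914	45499.5377175021
M008	11356.2468547041	12745.1655592901	10109.0027172888	14268.2772747807	10615.071123746	26462.5123353349
M009	3179.31401331243	6318.98552885203	4190.17819865499	912.550406731696	856.398370956461	1114.76127713071
M010	9153.2429866304	30366.8300790214	18485.1736652482	10709.5157339382	18131.5569973576	11699.4580479048
M011	15617.3341165605	10293.3344807091	12903.7269162656	12562.6229076927	5259.04779596859	13825.418344763
M012	16238.6793547331	18413.4890119367	16164.827390578	14220.7014764507	13553.0582715911	10823.6537620526
M013	4583.8537923073	7755.25403716205	4657.71080611384	4257.56347007898	6296.79456686065	4226.66227053512
M014	4013.36349146551	21372.7408717306	8070.49602839831	8076.40593274494	13496.3411812512	17083.6478531987
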