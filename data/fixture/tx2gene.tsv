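G0000.T1	G0000
G0000.T2	G0000
G0000.T3	G0000
G0001.T1	G0001
G0001.T2	G0001
G0001.T3	G0001
G0002.T1	G0002
G0002.T2	G0002
G0002.T3	G0002
G0003.T1	G0003
G0004.T1	G0004
G0004.T2	G0004
G0004.T3	G0004
G0005.T1	G0005
G0006.T1	G0006
G0006.T2	G0006
G0007.T1	G0007
G0007.T2	G0007
G0007.T3	G0007
G0008.T1	G0008
G0008.T2	G0008
G0008.T3	G0008
G0009.T1	G0009
G0009.T2	G0009
G0010.T1	G0010
G0010.T2	G0010
G0011.T1	G0011
G0011.T2	G0011
G0011.T3	G0011
G0012.T1	G0012
G0012.T2	G0012
G0012.T3	G0012
G0013.T1	G0013
G0013.T2	G0013
G0013.T3	G0013
G0014.T1	G0014
G0014.T2	G0014
G0015.T1	G0015
G0016.T1	G0016
G0017.T1	G0017
G0017.T2	G0017
G0017.T3	G0017
G0018.T1	G0018
G0019.T1	G0019
G0019.T2	G0019
G0020.T1	G0020
G0020.T2	G0020
G0021.T1	G0021
G0021.T2	G0021
G0021.T3	G0021
G0022.T1	G0022
G0023.T1	G0023
G0023.T2	G0023
G0024.T1	G0024
G0025.T1	G0025
G0025.T2	G0025
G0026.T1	G0026
G0027.T1	G0027
G0027.T2	G0027
G0028.T1	G0028
G0028.T2	G0028
G0029.T1	G0029
G0029.T2	G0029
G0030.T1	G0030
G0030.T2	G0030
G0031.T1	G0031
G0031.T2	G0031
G0031.T3	G0031
G0032.T1	G0032
G0032.T2	G0032
G0032.T3	G0032
G0033.T1	G0033
G0034.T1	G0034
G0034.T2	G0034
G0035.T1	G0035
G0035.T2	G0035
G0036.T1	G0036
G0036.T2	G0036
G0037.T1	G0037
G0038.T1	G0038
G0039.T1	G0039
G0039.T2	G0039
G0040.T1	G0040
G0041.T1	G0041
G0041.T2	G0041
G0041.T3	G0041
G0042.T1	G0042
G0043.T1	G0043
G0044.T1	G0044
G0044.T2	G0044
G0045.T1	G0045
G0045.T2	G0045
G0046.T1	G0046
G0047.T1	G0047
G0047.T2	G0047
G0048.T1	G0048
G0049.T1	G0049
G0049.T2	G0049
G0050.T1	G0050
G0050.T2	G0050
G0050.T3	G0050
G0051.T1	G0051
G0051.T2	G0051
G0052.T1	G0052
G0052.T2	G0052
G0053.T1	G0053
G0054.T1	G0054
G0054.T2	G0054
G0055.T1	G0055
G0056.T1	G0056
G0056.T2	G0056
G0056.T3	G0056
G0057.T1	G0057
G0057.T2	G0057
G0057.T3	G0057
G0058.T1	G0058
G0058.T2	G0058
G0059.T1	G0059
G0059.T2	G0059
G0059.T3	G0059
G0060.T1	G0060
G0060.T2	G0060
G0060.T3	G0060
G0061.T1	G0061
G0061.T2	G0061
G0062.T1	G0062
G0063.T1	G0063
G0063.T2	G0063
G0064.T1	G0064
G0065.T1	G0065
G0065.T2	G0065
G0065.T3	G0065
G0066.T1	G0066
G0067.T1	G0067
G0068.T1	G0068
G0069.T1	G0069
G0069.T2	G0069
G0070.T1	G0070
G0070.T2	G0070
G0070.T3	G0070
G0071.T1	G0071
G0071.T2	G0071
G0071.T3	G0071
G0072.T1	G0072
G0073.T1	G0073
G0073.T2	G0073
G0074.T1	G0074
G0075.T1	G0075
G0075.T2	G0075
G0076.T1	G0076
G0076.T2	G0076
G0077.T1	G0077
G0077.T2	G0077
G0077.T3	G0077
G0078.T1	G0078
G0079.T1	G0079
G0080.T1	G0080
G0081.T1	G0081
G0081.T2	G0081
G0082.T1	G0082
G0082.T2	G0082
G0082.T3	G0082
G0083.T1	G0083
G0083.T2	G0083
G0084.T1	G0084
G0084.T2	G0084
G0085.T1	G0085
G0085.T2	G0085
G0086.T1	G0086
G0086.T2	G0086
G0086.T3	G0086
G0087.T1	G0087
G0087.T2	G0087
G0087.T3	G0087
G0088.T1	G0088
G0088.T2	G0088
G0089.T1	G0089
G0090.T1	G0090
G0091.T1	G0091
G0091.T2	G0091
G0092.T1	G0092
G0092.T2	G0092
G0093.T1	G0093
G0094.T1	G0094
G0095.T1	G0095
G0095.T2	G0095
G0096.T1	G0096
G0097.T1	G0097
G0098.T1	G0098
G0098.T2	G0098
G0098.T3	G0098
G0099.T1	G0099
G0099.T2	G0099
G0099.T3	G0099
G0100.T1	G0100
G0100.T2	G0100
G0100.T3	G0100
G0101.T1	G0101
G0102.T1	G0102
G0102.T2	G0102
G0103.T1	G0103
G0104.T1	G0104
G0105.T1	G0105
G0105.T2	G0105
G0106.T1	G0106
G0106.T2	G0106
G0107.T1	G0107
G0108.T1	G0108
G0108.T2	G0108
G0108.T3	G0108
G0109.T1	G0109
G0109.T2	G0109
G0109.T3	G0109
G0110.T1	G0110
G0111.T1	G0111
G0111.T2	G0111
G0112.T1	G0112
G0113.T1	G0113
G0114.T1	G0114
G0114.T2	G0114
G0114.T3	G0114
G0115.T1	G0115
G0116.T1	G0116
G0116.T2	G0116
G0116.T3	G0116
G0117.T1	G0117
G0117.T2	G0117
G0118.T1	G0118
G0119.T1	G0119
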