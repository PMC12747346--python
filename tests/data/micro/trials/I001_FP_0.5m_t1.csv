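time_s,fz_left_n,fz_right_n
0.000000,0.452474,0.435400
0.005000,3.213500,3.092241
0.010000,1.148484,1.105147
0.015000,14.296844,13.757364
0.020000,-6.523107,-6.276963
0.025000,-7.577836,-7.291892
0.030000,5.504939,5.297214
0.035000,-1.806061,-1.737911
0.040000,-5.866105,-5.644752
0.045000,-17.707348,-17.039174
0.050000,0.018643,0.017939
0.055000,-5.426536,-5.221769
0.060000,10.528096,10.130826
0.065000,-10.255277,-9.868302
0.070000,4.150472,3.993857
0.075000,-0.279665,-0.269112
0.080000,-6.274546,-6.037781
0.085000,12.517742,12.045394
0.090000,14.258044,13.720027
0.095000,-2.596629,-2.498647
0.100000,-1.681470,-1.618021
0.105000,28.123638,27.062414
0.110000,104.977724,101.016469
0.115000,142.582238,137.202005
0.120000,203.070743,195.408021
0.125000,235.713170,226.818711
0.130000,293.045121,281.987283
0.135000,340.017296,327.186998
0.140000,388.408354,373.752056
0.145000,427.216790,411.096085
0.150000,473.020969,455.171878
0.155000,543.697498,523.181481
0.160000,631.415515,607.589525
0.165000,696.235605,669.963677
0.170000,783.460568,753.897271
0.175000,834.005080,802.534525
0.180000,938.227237,902.823937
0.185000,1002.402954,964.578031
0.190000,1069.121965,1028.779450
0.195000,1130.800477,1088.130571
0.200000,1199.041854,1153.796911
0.205000,1269.569415,1221.663167
0.210000,1345.857333,1295.072418
0.215000,1405.436523,1352.403432
0.220000,1469.404203,1413.957339
0.225000,1534.350452,1476.452890
0.230000,1589.652323,1529.667986
0.235000,1647.334927,1585.173980
0.240000,1692.371654,1628.511281
0.245000,1734.041926,1668.609156
0.250000,1805.920610,1737.775552
0.255000,1851.042614,1781.194912
0.260000,1865.380230,1794.991508
0.265000,1920.084728,1847.631773
0.270000,1982.124194,1907.330227
0.275000,2006.863236,1931.135759
0.280000,2036.338172,1959.498480
0.285000,2032.871231,1956.162362
0.290000,2076.805094,1998.438413
0.295000,2095.287632,2016.223527
0.300000,2120.683012,2040.660631
0.305000,2136.621542,2055.997733
0.310000,2159.940027,2078.436313
0.315000,2154.167690,2072.881790
0.320000,2163.018961,2081.399065
0.325000,2158.643643,2077.188847
0.330000,2152.481269,2071.259005
0.335000,2165.989879,2084.257878
0.340000,2165.396694,2083.687076
0.345000,2143.737971,2062.845629
0.350000,2143.413337,2062.533244
0.355000,2108.384797,2028.826480
0.360000,2096.824934,2017.702820
0.365000,2048.397436,1971.102697
0.370000,2044.261395,1967.122727
0.375000,2027.455152,1950.950654
0.380000,1970.697590,1896.334796
0.385000,1946.059940,1872.626830
0.390000,1906.082542,1834.157949
0.395000,1857.424781,1787.336252
0.400000,1817.992370,1749.391794
0.405000,1766.602412,1699.940996
0.410000,1711.728856,1647.138054
0.415000,1666.109106,1603.239730
0.420000,1608.808564,1548.101381
0.425000,1555.653412,1496.951999
0.430000,1474.238763,1418.609470
0.435000,1430.772849,1376.783710
0.440000,1382.077099,1329.925458
0.445000,1313.436359,1263.874825
0.450000,1252.289960,1205.035739
0.455000,1172.177967,1127.946711
0.460000,1113.466550,1071.450726
0.465000,1048.744871,1009.171271
0.470000,957.000257,920.888571
0.475000,887.953811,854.447541
0.480000,844.069632,812.219299
0.485000,737.104531,709.290445
0.490000,648.899703,624.413960
0.495000,607.108983,584.200181
0.500000,518.502385,498.937087
0.505000,464.612397,447.080597
0.510000,466.706033,449.095231
0.515000,482.457603,464.252428
0.520000,465.406191,447.844438
0.525000,471.143035,453.364807
0.530000,464.849986,447.309221
0.535000,479.705184,461.603869
0.540000,478.337323,460.287623
0.545000,461.460007,444.047161
0.550000,493.399097,474.781053
0.555000,469.176150,451.472141
0.560000,474.646739,456.736301
0.565000,498.856557,480.032580
0.570000,476.792203,458.800808
0.575000,473.516339,455.648555
0.580000,473.148843,455.294927
0.585000,486.569780,468.209435
0.590000,473.078889,455.227613
0.595000,459.396397,442.061419
0.600000,465.989691,448.405920
0.605000,472.371376,454.546797
0.610000,477.001720,459.002418
0.615000,463.091013,445.616622
0.620000,479.866061,461.758676
0.625000,473.767909,455.890633
0.630000,468.282215,450.611938
0.635000,475.812223,457.857806
0.640000,496.739677,477.995578
0.645000,475.030032,457.105131
0.650000,476.988164,458.989374
0.655000,486.708646,468.343061
0.660000,476.505860,458.525269
0.665000,482.953900,464.729997
0.670000,482.558970,464.349970
0.675000,465.940926,448.358996
0.680000,483.683529,465.432095
0.685000,472.204831,454.386536
0.690000,474.700739,456.788263
0.695000,477.958620,459.923211
0.700000,467.129431,449.502652
0.705000,485.558825,467.236628
0.710000,486.374703,468.021719
0.715000,500.131462,481.259376
0.720000,473.492814,455.625918
0.725000,475.098525,457.171039
0.730000,495.075612,476.394306
0.735000,461.972090,444.539920
0.740000,472.616668,454.782833
0.745000,492.863849,474.266002
0.750000,470.540550,452.785056
0.755000,501.466640,482.544173
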