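time_s,fz_left_n,fz_right_n
0.000000,8.064734,7.876093
0.005000,-3.525160,-3.442703
0.010000,-3.656716,-3.571182
0.015000,-7.918741,-7.733515
0.020000,3.145192,3.071623
0.025000,3.772580,3.684336
0.030000,16.236661,15.856872
0.035000,3.573848,3.490253
0.040000,0.220910,0.215743
0.045000,5.132150,5.012104
0.050000,-14.807879,-14.461510
0.055000,-8.173162,-7.981985
0.060000,2.336645,2.281989
0.065000,-8.561896,-8.361626
0.070000,8.016131,7.828627
0.075000,-17.502902,-17.093494
0.080000,5.596080,5.465183
0.085000,5.822905,5.686702
0.090000,3.646039,3.560755
0.095000,-6.486533,-6.334807
0.100000,0.842749,0.823036
0.105000,39.358482,38.437853
0.110000,72.035428,70.350458
0.115000,117.216658,114.474861
0.120000,142.888525,139.546241
0.125000,178.206896,174.038485
0.130000,218.697086,213.581575
0.135000,260.482844,254.389929
0.140000,284.369891,277.718237
0.145000,334.941004,327.106448
0.150000,370.957527,362.280514
0.155000,443.006833,432.644525
0.160000,555.427835,542.435904
0.165000,612.087409,597.770162
0.170000,699.296747,682.939600
0.175000,776.976986,758.802831
0.180000,876.148167,855.654314
0.185000,948.630227,926.440957
0.190000,1017.178610,993.385935
0.195000,1104.002924,1078.179354
0.200000,1186.293036,1158.544631
0.205000,1263.602212,1234.045479
0.210000,1345.199675,1313.734308
0.215000,1405.601161,1372.722951
0.220000,1487.774387,1452.974076
0.225000,1537.729332,1501.760532
0.230000,1606.114985,1568.546586
0.235000,1666.681593,1627.696489
0.240000,1743.389962,1702.610584
0.245000,1794.013620,1752.050112
0.250000,1846.679013,1803.483616
0.255000,1919.729588,1874.825476
0.260000,1958.096963,1912.295406
0.265000,1992.104905,1945.507872
0.270000,2025.039186,1977.671793
0.275000,2070.069593,2021.648900
0.280000,2120.555454,2070.953854
0.285000,2161.574847,2111.013769
0.290000,2184.453535,2133.357305
0.295000,2203.209478,2151.674530
0.300000,2231.039138,2178.853230
0.305000,2248.812193,2196.210558
0.310000,2262.059912,2209.148402
0.315000,2289.348384,2235.798573
0.320000,2292.496820,2238.873365
0.325000,2303.870490,2249.980995
0.330000,2305.516926,2251.588920
0.335000,2294.541231,2240.869955
0.340000,2293.770858,2240.117602
0.345000,2277.622838,2224.347298
0.350000,2276.759985,2223.504627
0.355000,2260.230343,2207.361628
0.360000,2236.432086,2184.120033
0.365000,2215.782287,2163.953250
0.370000,2178.863379,2127.897907
0.375000,2151.785836,2101.453731
0.380000,2112.014863,2062.613034
0.385000,2068.157846,2019.781871
0.390000,2037.722647,1990.058577
0.395000,1999.916971,1953.137207
0.400000,1955.768307,1910.021218
0.405000,1893.725748,1849.429888
0.410000,1859.089380,1815.603694
0.415000,1794.068612,1752.103818
0.420000,1721.363091,1681.098940
0.425000,1660.725230,1621.879451
0.430000,1603.563336,1566.054622
0.435000,1547.261076,1511.069320
0.440000,1473.400426,1438.936333
0.445000,1408.310521,1375.368938
0.450000,1334.076911,1302.871715
0.455000,1253.405510,1224.087286
0.460000,1170.425416,1143.048167
0.465000,1112.925763,1086.893481
0.470000,1024.091638,1000.137261
0.475000,939.681080,917.701138
0.480000,853.350260,833.389670
0.485000,768.759356,750.777419
0.490000,689.148737,673.028961
0.495000,610.358540,596.081733
0.500000,531.454368,519.023197
0.505000,448.549725,438.057764
0.510000,364.586459,356.058470
0.515000,360.106231,351.683039
0.520000,361.015249,352.570794
0.525000,368.571815,359.950606
0.530000,352.347340,344.105635
0.535000,362.861365,354.373728
0.540000,379.297636,370.425541
0.545000,362.518200,354.038590
0.550000,356.166385,347.835349
0.555000,375.313191,366.534295
0.560000,354.293603,346.006373
0.565000,386.818747,377.770727
0.570000,374.351602,365.595199
0.575000,373.339466,364.606738
0.580000,367.538557,358.941517
0.585000,373.528549,364.791398
0.590000,380.064090,371.174067
0.595000,362.339101,353.863681
0.600000,359.821852,351.405312
0.605000,368.648913,360.025900
0.610000,361.912424,353.446983
0.615000,366.706715,358.129132
0.620000,367.779164,359.176496
0.625000,374.754200,365.988380
0.630000,369.772157,361.122871
0.635000,352.701767,344.451772
0.640000,357.754149,349.385974
0.645000,362.551870,354.071473
0.650000,373.917733,365.171478
0.655000,363.964020,355.450591
0.660000,363.525721,355.022544
0.665000,354.870034,346.569321
0.670000,369.857824,361.206534
0.675000,361.127149,352.680077
0.680000,365.998276,357.437264
0.685000,356.355061,348.019613
0.690000,370.175650,361.516926
0.695000,371.643412,362.950355
0.700000,362.221102,353.748441
0.705000,377.908317,369.068719
0.710000,358.945565,350.549522
0.715000,365.886551,357.328152
0.720000,377.375752,368.548611
0.725000,366.919200,358.336647
0.730000,355.364857,347.052570
0.735000,368.033785,359.425161
0.740000,360.663092,352.226874
0.745000,369.748080,361.099357
0.750000,372.775412,364.055877
0.755000,383.855577,374.876868
0.760000,370.064467,361.408343
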