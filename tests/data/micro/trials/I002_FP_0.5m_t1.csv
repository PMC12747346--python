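time_s,fz_left_n,fz_right_n
0.000000,-3.719954,-3.480082
0.005000,12.250634,11.460683
0.010000,6.769552,6.333035
0.015000,-2.211951,-2.069319
0.020000,-3.384638,-3.166388
0.025000,4.162623,3.894207
0.030000,3.525159,3.297848
0.035000,14.768285,13.815990
0.040000,-7.131499,-6.671643
0.045000,0.830816,0.777243
0.050000,2.108050,1.972118
0.055000,2.017041,1.886978
0.060000,-5.032328,-4.707831
0.065000,-4.089897,-3.826170
0.070000,-9.851646,-9.216387
0.075000,-4.249868,-3.975826
0.080000,4.173827,3.904688
0.085000,4.001327,3.743312
0.090000,-1.944724,-1.819323
0.095000,-7.066369,-6.610712
0.100000,-1.068663,-0.999753
0.105000,42.866692,40.102543
0.110000,80.376510,75.193636
0.115000,103.136621,96.486119
0.120000,151.695083,141.913412
0.125000,186.565771,174.535553
0.130000,230.235716,215.389552
0.135000,265.116856,248.021471
0.140000,294.885490,275.870551
0.145000,337.530113,315.765344
0.150000,383.468359,358.741379
0.155000,459.949583,430.290905
0.160000,545.678373,510.491693
0.165000,611.628485,572.189180
0.170000,692.853453,648.176563
0.175000,773.578012,723.695804
0.180000,862.009608,806.425114
0.185000,926.063086,866.348267
0.190000,1016.303390,950.769655
0.195000,1075.141369,1005.813616
0.200000,1154.113545,1079.693473
0.205000,1235.327196,1155.670269
0.210000,1303.280507,1219.241784
0.215000,1368.397487,1280.159860
0.220000,1445.409924,1352.206347
0.225000,1523.156979,1424.940082
0.230000,1583.307190,1481.211659
0.235000,1632.923683,1527.628759
0.240000,1692.970669,1583.803768
0.245000,1738.124278,1626.045762
0.250000,1797.412331,1681.510775
0.255000,1865.752746,1745.444433
0.260000,1902.716213,1780.024405
0.265000,1955.386443,1829.298329
0.270000,2014.645853,1884.736547
0.275000,2046.213026,1914.268192
0.280000,2078.068762,1944.069792
0.285000,2124.739621,1987.731199
0.290000,2159.474118,2020.225930
0.295000,2161.060471,2021.709992
0.300000,2209.670565,2067.185588
0.305000,2225.160602,2081.676789
0.310000,2246.492655,2101.633299
0.315000,2242.081721,2097.506793
0.320000,2277.992668,2131.102114
0.325000,2276.833277,2130.017483
0.330000,2305.659110,2156.984556
0.335000,2291.282735,2143.535204
0.340000,2293.722167,2145.817336
0.345000,2279.699109,2132.698519
0.350000,2278.237943,2131.331573
0.355000,2266.568471,2120.414576
0.360000,2250.448687,2105.334236
0.365000,2240.223838,2095.768710
0.370000,2214.101851,2071.331134
0.375000,2197.294693,2055.607742
0.380000,2158.856158,2019.647818
0.385000,2134.029607,1996.422144
0.390000,2099.237259,1963.873292
0.395000,2074.064008,1940.323274
0.400000,2028.124547,1897.346102
0.405000,1984.651030,1856.675864
0.410000,1923.216956,1799.203210
0.415000,1894.738795,1772.561391
0.420000,1830.564793,1712.525485
0.425000,1770.602425,1656.429638
0.430000,1718.202417,1607.408511
0.435000,1655.363560,1548.621657
0.440000,1597.658779,1494.637823
0.445000,1533.191247,1434.327315
0.450000,1467.000287,1372.404511
0.455000,1406.542570,1315.845255
0.460000,1331.624063,1245.757678
0.465000,1267.983946,1186.221231
0.470000,1186.839261,1110.308954
0.475000,1107.481147,1036.068047
0.480000,1042.811752,975.568692
0.485000,956.559838,894.878514
0.490000,894.896096,837.191001
0.495000,802.321086,750.585455
0.500000,731.933861,684.736971
0.505000,646.998139,605.278112
0.510000,555.641015,519.811920
0.515000,502.791809,470.370560
0.520000,420.474623,393.361388
0.525000,367.439338,343.745948
0.530000,360.282091,337.050218
0.535000,372.484063,348.465377
0.540000,371.788186,347.814372
0.545000,368.586711,344.819336
0.550000,359.583867,336.397017
0.555000,369.918083,346.064858
0.560000,372.761251,348.724691
0.565000,365.151381,341.605525
0.570000,379.478214,355.008528
0.575000,378.795476,354.369815
0.580000,370.922349,347.004367
0.585000,383.392617,358.670521
0.590000,378.269121,353.877400
0.595000,377.330394,352.999204
0.600000,358.260473,335.158959
0.605000,392.830398,367.499730
0.610000,381.477612,356.879000
0.615000,369.331571,345.516165
0.620000,370.071433,346.208320
0.625000,356.224682,333.254441
0.630000,382.090255,357.452139
0.635000,372.216392,348.214966
0.640000,361.966065,338.625606
0.645000,372.226709,348.224618
0.650000,366.873098,343.216221
0.655000,386.587015,361.658936
0.660000,359.006904,335.857258
0.665000,361.296023,337.998769
0.670000,367.567329,343.865686
0.675000,369.169342,345.364397
0.680000,380.916761,356.354314
0.685000,373.483958,349.400797
0.690000,362.988699,339.582297
0.695000,364.930755,341.399125
0.700000,366.454532,342.824645
0.705000,377.417563,353.080753
0.710000,385.335745,360.488351
0.715000,383.312022,358.595123
0.720000,386.252150,361.345664
0.725000,384.306392,359.525373
0.730000,379.464203,354.995420
0.735000,368.759618,344.981093
0.740000,382.292250,357.641108
0.745000,359.887101,336.680698
0.750000,369.310740,345.496678
0.755000,374.033855,349.915235
0.760000,375.954255,351.711803
0.765000,369.042063,345.245325
0.770000,374.120848,349.996618
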