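time_s,fz_left_n,fz_right_n
0.000000,8.305650,7.081809
0.005000,0.301561,0.257126
0.010000,2.322832,1.980561
0.015000,22.533518,19.213196
0.020000,13.222128,11.273843
0.025000,8.860798,7.555156
0.030000,2.008025,1.712142
0.035000,5.250825,4.477114
0.040000,1.385349,1.181217
0.045000,-14.235811,-12.138159
0.050000,8.263428,7.045809
0.055000,3.869855,3.299630
0.060000,-12.601317,-10.744508
0.065000,-5.992986,-5.109917
0.070000,-2.313540,-1.972639
0.075000,3.038946,2.591156
0.080000,16.130508,13.753672
0.085000,0.165365,0.140999
0.090000,-18.112030,-15.443216
0.095000,6.062750,5.169401
0.100000,-1.568392,-1.337289
0.105000,30.390415,25.912376
0.110000,72.012669,61.401575
0.115000,130.021569,110.862843
0.120000,190.132131,162.116091
0.125000,226.177746,192.850371
0.130000,285.499294,243.430868
0.135000,323.931865,276.200385
0.140000,374.919130,319.674658
0.145000,426.414167,363.581882
0.150000,471.907931,402.372123
0.155000,551.447204,470.191255
0.160000,673.754527,574.476549
0.165000,731.291153,623.535131
0.170000,841.176433,717.228774
0.175000,925.547629,789.167844
0.180000,1037.035805,884.228196
0.185000,1103.008001,940.479364
0.190000,1193.095462,1017.292405
0.195000,1277.588109,1089.335029
0.200000,1358.553010,1158.369722
0.205000,1446.760775,1233.580040
0.210000,1531.751970,1306.047751
0.215000,1596.046005,1360.868036
0.220000,1661.158355,1416.386058
0.225000,1742.862022,1486.050659
0.230000,1810.040076,1543.330002
0.235000,1878.229331,1601.471545
0.240000,1921.408822,1638.288522
0.245000,1980.540127,1688.706807
0.250000,2039.884078,1739.306405
0.255000,2066.957755,1762.390766
0.260000,2115.668920,1803.924323
0.265000,2148.986452,1832.332504
0.270000,2170.011948,1850.259886
0.275000,2208.738495,1883.280061
0.280000,2241.836559,1911.501114
0.285000,2268.952459,1934.621476
0.290000,2246.263376,1915.275638
0.295000,2275.195156,1939.944309
0.300000,2278.679660,1942.915370
0.305000,2276.434513,1941.001046
0.310000,2252.837833,1920.881345
0.315000,2246.702930,1915.650423
0.320000,2220.002701,1892.884483
0.325000,2208.004636,1882.654337
0.330000,2186.221365,1864.080839
0.335000,2140.261405,1824.893096
0.340000,2107.535947,1796.989746
0.345000,2071.850222,1766.562326
0.350000,2024.466498,1726.160611
0.355000,1961.246258,1672.255897
0.360000,1925.698137,1641.945805
0.365000,1858.925090,1585.011791
0.370000,1793.493458,1529.221534
0.375000,1726.411849,1472.024425
0.380000,1663.051628,1418.000356
0.385000,1593.340877,1358.561510
0.390000,1496.022316,1275.582875
0.395000,1420.987244,1211.604248
0.400000,1331.562926,1135.356637
0.405000,1267.926194,1081.096801
0.410000,1181.307146,1007.241101
0.415000,1086.407426,926.324890
0.420000,989.662181,843.835093
0.425000,920.862424,785.173006
0.430000,831.100320,708.637381
0.435000,737.460908,628.795771
0.440000,629.047072,536.356754
0.445000,535.292440,456.416901
0.450000,467.786345,398.857854
0.455000,465.237435,396.684527
0.460000,455.045657,387.994511
0.465000,460.846030,392.940197
0.470000,474.113136,404.252390
0.475000,466.478375,397.742614
0.480000,462.058087,393.973657
0.485000,464.155576,395.762080
0.490000,482.829590,411.684471
0.495000,480.379903,409.595747
0.500000,476.789369,406.534279
0.505000,468.153272,399.170715
0.510000,455.216051,388.139798
0.515000,468.317179,399.310469
0.520000,463.496678,395.200271
0.525000,472.287428,402.695701
0.530000,476.055317,405.908390
0.535000,460.139026,392.337371
0.540000,478.805827,408.253611
0.545000,467.046401,398.226942
0.550000,467.346051,398.482438
0.555000,461.297912,393.325494
0.560000,464.770663,396.286534
0.565000,467.378803,398.510364
0.570000,464.643213,396.177864
0.575000,463.551378,395.246911
0.580000,462.827734,394.629896
0.585000,485.517744,413.976525
0.590000,464.588955,396.131601
0.595000,473.558191,403.779217
0.600000,467.228822,398.382482
0.605000,439.254579,374.530254
0.610000,495.631436,422.599960
0.615000,466.519882,397.778005
0.620000,461.359865,393.378319
0.625000,478.777409,408.229381
0.630000,480.359231,409.578121
0.635000,461.185791,393.229894
0.640000,458.743542,391.147512
0.645000,458.235488,390.714319
0.650000,469.770530,400.549668
0.655000,468.029797,399.065433
0.660000,473.821914,404.004080
0.665000,465.444133,396.860768
0.670000,461.724990,393.689642
0.675000,467.618927,398.715105
0.680000,461.175312,393.220959
0.685000,472.664435,403.017156
0.690000,470.395873,401.082867
0.695000,471.695457,402.190957
0.700000,470.726692,401.364940
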