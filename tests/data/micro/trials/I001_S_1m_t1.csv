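time_s,fz_left_n,fz_right_n
0.000000,7.540493,8.002876
0.005000,1.300739,1.380500
0.010000,-0.614935,-0.652642
0.015000,-0.055262,-0.058651
0.020000,-6.966672,-7.393868
0.025000,-1.097434,-1.164729
0.030000,0.436911,0.463702
0.035000,1.702554,1.806955
0.040000,-5.251594,-5.573621
0.045000,3.210521,3.407390
0.050000,-4.885528,-5.185108
0.055000,-4.232096,-4.491608
0.060000,0.664787,0.705551
0.065000,-3.884782,-4.122997
0.070000,-8.671733,-9.203483
0.075000,-4.445952,-4.718578
0.080000,-5.896173,-6.257726
0.085000,1.059299,1.124255
0.090000,5.633923,5.979395
0.095000,4.866028,5.164413
0.100000,-5.669755,-6.017424
0.105000,38.877050,41.260990
0.110000,86.047095,91.323500
0.115000,112.141602,119.018121
0.120000,174.826445,185.546798
0.125000,219.808685,233.287347
0.130000,257.289603,273.066594
0.135000,275.121059,291.991474
0.140000,337.581137,358.281602
0.145000,361.730186,383.911470
0.150000,426.951578,453.132236
0.155000,543.519684,576.848295
0.160000,691.817218,734.239429
0.165000,847.426112,899.390256
0.170000,971.265962,1030.823962
0.175000,1096.462933,1163.698008
0.180000,1243.770686,1320.038669
0.185000,1386.224495,1471.227741
0.190000,1497.980358,1589.836469
0.195000,1619.325819,1718.622831
0.200000,1745.321435,1852.344495
0.205000,1853.346536,1966.993691
0.210000,1967.017347,2087.634793
0.215000,2060.234327,2186.567836
0.220000,2139.511233,2270.705999
0.225000,2218.103460,2354.117500
0.230000,2306.934884,2448.396064
0.235000,2357.751544,2502.328800
0.240000,2411.286944,2559.146989
0.245000,2472.667973,2624.291900
0.250000,2502.935748,2656.415695
0.255000,2525.077168,2679.914827
0.260000,2564.094080,2721.324254
0.265000,2577.917288,2735.995101
0.270000,2562.207936,2719.322452
0.275000,2561.741310,2718.827213
0.280000,2543.940561,2699.934921
0.285000,2520.338225,2674.885292
0.290000,2482.506604,2634.733837
0.295000,2429.058931,2578.008754
0.300000,2388.615769,2535.085619
0.305000,2323.482504,2465.958383
0.310000,2257.001706,2395.400984
0.315000,2182.979477,2316.839715
0.320000,2098.069705,2226.723278
0.325000,2001.276421,2123.994633
0.330000,1875.125366,1990.107999
0.335000,1781.587820,1890.834733
0.340000,1678.082364,1780.982325
0.345000,1565.774329,1661.787565
0.350000,1426.714714,1514.200818
0.355000,1300.845121,1380.612905
0.360000,1190.129792,1263.108516
0.365000,1018.982565,1081.466546
0.370000,899.739348,954.911338
0.375000,756.853814,803.264068
0.380000,617.572176,655.441684
0.385000,475.600893,504.764726
0.390000,424.647678,450.687061
0.395000,427.275252,453.475758
0.400000,445.190900,472.489993
0.405000,434.364056,460.999247
0.410000,418.801466,444.482359
0.415000,421.440436,447.283151
0.420000,428.182649,454.438796
0.425000,441.818431,468.910724
0.430000,417.798233,443.417609
0.435000,422.740523,448.662960
0.440000,417.836206,443.457910
0.445000,429.392134,455.722447
0.450000,407.917770,432.931276
0.455000,420.600561,446.391776
0.460000,408.206234,433.237428
0.465000,421.693096,447.551304
0.470000,426.130639,452.260957
0.475000,416.015645,441.525712
0.480000,417.427178,443.023800
0.485000,428.959532,455.263318
0.490000,418.490817,444.152661
0.495000,424.136264,450.144287
0.500000,417.365931,442.958797
0.505000,411.541684,436.777408
0.510000,415.882641,441.384552
0.515000,437.066934,463.867865
0.520000,417.014376,442.585686
0.525000,419.885546,445.632916
0.530000,429.524860,455.863311
0.535000,422.561642,448.473109
0.540000,423.976638,449.974873
0.545000,438.766152,465.671279
0.550000,427.222329,453.419590
0.555000,412.666206,437.970885
0.560000,425.206766,451.280432
0.565000,414.460847,439.875574
0.570000,416.531177,442.072856
0.575000,428.469656,454.743402
0.580000,420.017568,445.773033
0.585000,416.980909,442.550166
0.590000,414.682916,440.111260
0.595000,420.649895,446.444134
0.600000,417.146627,442.726046
0.605000,427.600632,453.821090
0.610000,421.133701,446.957607
0.615000,418.123775,443.763113
0.620000,445.341146,472.649452
0.625000,422.114646,447.998704
0.630000,413.338842,438.684768
0.635000,408.984060,434.062951
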