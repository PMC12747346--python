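time_s,fz_left_n,fz_right_n
0.000000,-0.159708,-0.160733
0.005000,5.222475,5.256010
0.010000,-8.670535,-8.726211
0.015000,-4.009091,-4.034835
0.020000,-4.951399,-4.983193
0.025000,14.254579,14.346111
0.030000,1.255759,1.263823
0.035000,3.831812,3.856417
0.040000,9.654456,9.716450
0.045000,2.015461,2.028403
0.050000,-0.478432,-0.481505
0.055000,-3.690785,-3.714485
0.060000,-2.495463,-2.511487
0.065000,-0.293992,-0.295880
0.070000,-2.007487,-2.020378
0.075000,-1.964245,-1.976858
0.080000,16.471105,16.576871
0.085000,-11.452867,-11.526409
0.090000,-17.724941,-17.838758
0.095000,3.298705,3.319887
0.100000,11.909484,11.985958
0.105000,40.800781,41.062775
0.110000,93.403403,94.003173
0.115000,143.547730,144.469492
0.120000,170.374800,171.468826
0.125000,217.276170,218.671363
0.130000,251.445679,253.060285
0.135000,296.112909,298.014336
0.140000,341.209783,343.400790
0.145000,394.080860,396.611367
0.150000,443.665951,446.514859
0.155000,581.386305,585.119555
0.160000,711.874031,716.445180
0.165000,855.000512,860.490718
0.170000,998.788282,1005.201791
0.175000,1139.372038,1146.688275
0.180000,1278.054554,1286.261312
0.185000,1389.562373,1398.485155
0.190000,1517.915280,1527.662253
0.195000,1661.302143,1671.969845
0.200000,1762.718943,1774.037871
0.205000,1868.307316,1880.304257
0.210000,1951.414957,1963.945557
0.215000,2063.255376,2076.504135
0.220000,2141.801295,2155.554421
0.225000,2198.543571,2212.661055
0.230000,2265.505321,2280.052786
0.235000,2337.204453,2352.212318
0.240000,2366.352619,2381.547653
0.245000,2418.930456,2434.463108
0.250000,2435.104577,2450.741088
0.255000,2461.250777,2477.055179
0.260000,2468.878578,2484.731961
0.265000,2472.176387,2488.050947
0.270000,2425.833631,2441.410610
0.275000,2403.068007,2418.498802
0.280000,2379.377650,2394.656322
0.285000,2349.547837,2364.634963
0.290000,2284.382233,2299.050912
0.295000,2203.855490,2218.007084
0.300000,2149.968832,2163.774404
0.305000,2059.298839,2072.522193
0.310000,1980.651697,1993.370034
0.315000,1861.274741,1873.226524
0.320000,1773.728232,1785.117854
0.325000,1665.353590,1676.047307
0.330000,1526.289583,1536.090330
0.335000,1411.918609,1420.984947
0.340000,1285.412307,1293.666311
0.345000,1149.865023,1157.248639
0.350000,1003.535722,1009.979715
0.355000,879.724730,885.373697
0.360000,720.800927,725.429398
0.365000,585.668424,589.429170
0.370000,444.595553,447.450430
0.375000,434.252263,437.040722
0.380000,436.273845,439.075286
0.385000,415.407777,418.075230
0.390000,411.437233,414.079191
0.395000,433.007204,435.787669
0.400000,433.966767,436.753393
0.405000,443.116470,445.961849
0.410000,429.041333,431.796332
0.415000,429.590559,432.349084
0.420000,418.083581,420.768217
0.425000,434.401768,437.191187
0.430000,443.346082,446.192936
0.435000,427.531548,430.276852
0.440000,434.986996,437.780173
0.445000,441.239181,444.072505
0.450000,441.201521,444.034604
0.455000,439.071701,441.891108
0.460000,439.852559,442.676979
0.465000,401.898056,404.478759
0.470000,414.880897,417.544967
0.475000,434.192797,436.980874
0.480000,416.466772,419.141026
0.485000,439.396943,442.218438
0.490000,426.034622,428.770314
0.495000,417.457807,420.138424
0.500000,438.552909,441.368984
0.505000,425.407130,428.138792
0.510000,422.525020,425.238175
0.515000,437.414873,440.223641
0.520000,429.066144,431.821302
0.525000,420.569083,423.269679
0.530000,421.563810,424.270793
0.535000,416.777647,419.453897
0.540000,444.942918,447.800025
0.545000,442.250038,445.089854
0.550000,431.248157,434.017326
0.555000,424.941786,427.670460
0.560000,435.014105,437.807456
0.565000,429.113327,431.868788
0.570000,437.622824,440.432926
0.575000,436.265994,439.067384
0.580000,431.337084,434.106824
0.585000,428.452649,431.203868
0.590000,436.040449,438.840391
0.595000,430.856098,433.622749
0.600000,416.556088,419.230915
0.605000,433.283021,436.065256
0.610000,446.357821,449.224014
0.615000,427.636739,430.382718
0.620000,433.125669,435.906894
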