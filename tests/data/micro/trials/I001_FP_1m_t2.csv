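time_s,fz_left_n,fz_right_n
0.000000,2.983939,3.070246
0.005000,-1.616494,-1.663248
0.010000,0.373043,0.383833
0.015000,-6.328916,-6.511971
0.020000,13.098849,13.477715
0.025000,-0.088248,-0.090801
0.030000,-3.866005,-3.977824
0.035000,0.057653,0.059321
0.040000,-9.717728,-9.998799
0.045000,-4.676071,-4.811320
0.050000,1.441572,1.483268
0.055000,1.713192,1.762744
0.060000,15.676019,16.129426
0.065000,-1.170676,-1.204536
0.070000,2.650871,2.727543
0.075000,-9.636207,-9.914921
0.080000,10.860607,11.174735
0.085000,-2.992896,-3.079462
0.090000,17.749707,18.263093
0.095000,-16.864402,-17.352181
0.100000,12.529419,12.891815
0.105000,43.749121,45.014504
0.110000,89.981742,92.584340
0.115000,127.810405,131.507144
0.120000,190.318860,195.823570
0.125000,242.062916,249.064250
0.130000,265.033671,272.699402
0.135000,325.681132,335.101007
0.140000,363.171319,373.675546
0.145000,418.784822,430.897592
0.150000,465.021483,478.471584
0.155000,641.913877,660.480345
0.160000,827.006824,850.926850
0.165000,1032.506815,1062.370642
0.170000,1230.599637,1266.193025
0.175000,1400.299413,1440.801131
0.180000,1597.514617,1643.720511
0.185000,1788.336328,1840.061475
0.190000,1959.255295,2015.924037
0.195000,2134.388356,2196.122578
0.200000,2319.456301,2386.543357
0.205000,2504.941705,2577.393669
0.210000,2668.967112,2746.163284
0.215000,2848.987698,2931.390715
0.220000,2989.683333,3076.155776
0.225000,3183.504929,3275.583393
0.230000,3320.362143,3416.399012
0.235000,3462.209098,3562.348693
0.240000,3628.410308,3733.357043
0.245000,3752.921992,3861.470055
0.250000,3887.184946,3999.616378
0.255000,4020.186102,4136.464408
0.260000,4126.280508,4245.627447
0.265000,4276.339243,4400.026423
0.270000,4381.540306,4508.270282
0.275000,4486.341601,4616.102808
0.280000,4581.596367,4714.112686
0.285000,4699.824296,4835.760194
0.290000,4773.269467,4911.329664
0.295000,4851.028755,4991.338032
0.300000,4936.300733,5079.076384
0.305000,4990.729774,5135.079710
0.310000,5050.680024,5196.763937
0.315000,5116.488633,5264.475969
0.320000,5160.181524,5309.432616
0.325000,5197.003115,5347.319221
0.330000,5227.401768,5378.597113
0.335000,5244.647422,5396.341573
0.340000,5251.252355,5403.137545
0.345000,5266.931458,5419.270144
0.350000,5284.079295,5436.913958
0.355000,5257.625341,5409.694860
0.360000,5254.793620,5406.781236
0.365000,5216.320225,5367.195051
0.370000,5195.394487,5345.664065
0.375000,5148.427486,5297.338609
0.380000,5111.995470,5259.852847
0.385000,5052.806470,5198.951888
0.390000,4981.898701,5125.993210
0.395000,4928.124826,5070.664000
0.400000,4865.942979,5006.683630
0.405000,4770.430750,4908.408842
0.410000,4683.889058,4819.364051
0.415000,4590.424957,4723.196630
0.420000,4489.435835,4619.286539
0.425000,4394.017567,4521.108430
0.430000,4274.517218,4398.151699
0.435000,4151.322672,4271.393921
0.440000,4017.834472,4134.044761
0.445000,3910.752478,4023.865568
0.450000,3759.838387,3868.586496
0.455000,3616.619338,3721.225035
0.460000,3461.586959,3561.708560
0.465000,3327.251846,3423.487990
0.470000,3168.140549,3259.774620
0.475000,3006.052420,3092.998316
0.480000,2827.174277,2908.946371
0.485000,2659.590167,2736.515123
0.490000,2499.806808,2572.110253
0.495000,2348.989363,2416.930621
0.500000,2149.659470,2211.835388
0.505000,1977.753145,2034.956911
0.510000,1805.744193,1857.972838
0.515000,1616.610427,1663.368641
0.520000,1418.760346,1459.796021
0.525000,1212.354435,1247.420105
0.530000,1042.379500,1072.528881
0.535000,856.290582,881.057599
0.540000,663.113484,682.293121
0.545000,463.779323,477.193497
0.550000,450.818488,463.857788
0.555000,468.415450,481.963717
0.560000,473.493571,487.188716
0.565000,462.975835,476.366769
0.570000,461.087993,474.424324
0.575000,466.161408,479.644480
0.580000,450.084576,463.102648
0.585000,456.806642,470.019140
0.590000,462.137412,475.504096
0.595000,449.978205,462.993201
0.600000,469.418562,482.995843
0.605000,463.275793,476.675402
0.610000,469.073616,482.640920
0.615000,449.116775,462.106855
0.620000,465.604763,479.071735
0.625000,454.286443,467.426048
0.630000,465.797711,479.270264
0.635000,453.636656,466.757467
0.640000,465.429467,478.891369
0.645000,485.306164,499.342972
0.650000,455.580383,468.757413
0.655000,466.091451,479.572500
0.660000,466.863125,480.366494
0.665000,473.225858,486.913260
0.670000,469.847561,483.437250
0.675000,470.531474,484.140944
0.680000,450.741501,463.778574
0.685000,458.732075,472.000263
0.690000,450.497575,463.527593
0.695000,453.231961,466.341067
0.700000,475.624172,489.380942
0.705000,461.057032,474.392467
0.710000,452.371404,465.455619
0.715000,460.252895,473.565072
0.720000,472.417439,486.081458
0.725000,455.151617,468.316247
0.730000,459.957313,473.260940
0.735000,454.618000,467.767195
0.740000,454.212886,467.350363
0.745000,467.232283,480.746329
0.750000,475.347663,489.096435
0.755000,456.839667,470.053120
0.760000,478.243319,492.075844
0.765000,455.093471,468.256419
0.770000,480.879664,494.788441
0.775000,465.264442,478.721571
0.780000,481.240999,495.160227
0.785000,453.368069,466.481111
0.790000,471.063045,484.687891
0.795000,472.001043,485.653018
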