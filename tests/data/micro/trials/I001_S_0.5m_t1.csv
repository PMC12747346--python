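time_s,fz_left_n,fz_right_n
0.000000,5.695335,5.363206
0.005000,-6.510457,-6.130793
0.010000,-9.861235,-9.286167
0.015000,13.214632,12.444007
0.020000,0.435433,0.410040
0.025000,7.224400,6.803102
0.030000,-12.253337,-11.538771
0.035000,-3.884706,-3.658165
0.040000,-11.493692,-10.823426
0.045000,-6.905329,-6.502637
0.050000,8.039343,7.570521
0.055000,-13.180587,-12.411948
0.060000,-4.754658,-4.477385
0.065000,1.458096,1.373066
0.070000,-5.950927,-5.603892
0.075000,-2.245961,-2.114985
0.080000,-1.975079,-1.859900
0.085000,3.722397,3.505322
0.090000,-3.839160,-3.615275
0.095000,2.423748,2.282404
0.100000,0.505822,0.476324
0.105000,48.291173,45.475023
0.110000,91.025570,85.717320
0.115000,148.291793,139.644004
0.120000,172.137864,162.099467
0.125000,233.233169,219.631937
0.130000,263.484987,248.119589
0.135000,303.052942,285.380098
0.140000,366.874645,345.479972
0.145000,396.691133,373.557682
0.150000,441.664424,415.908308
0.155000,517.880937,487.680177
0.160000,596.483080,561.698555
0.165000,705.308172,664.177400
0.170000,773.160402,728.072757
0.175000,873.501268,822.562143
0.180000,965.026484,908.749971
0.185000,1028.312066,968.344989
0.190000,1098.625926,1034.558424
0.195000,1189.851516,1120.464100
0.200000,1268.984313,1194.982187
0.205000,1333.720805,1255.943503
0.210000,1407.860303,1325.759480
0.215000,1488.874113,1402.048886
0.220000,1554.993003,1464.311986
0.225000,1614.082184,1519.955319
0.230000,1661.218952,1564.343259
0.235000,1726.609576,1625.920561
0.240000,1787.452320,1683.215198
0.245000,1831.903007,1725.073697
0.250000,1876.641888,1767.203585
0.255000,1920.002361,1808.035447
0.260000,1962.283439,1847.850860
0.265000,1999.273465,1882.683775
0.270000,2034.735729,1916.078020
0.275000,2078.524517,1957.313220
0.280000,2086.772949,1965.080636
0.285000,2123.309615,1999.486629
0.290000,2136.530718,2011.936730
0.295000,2147.299073,2022.077117
0.300000,2147.740920,2022.493197
0.305000,2155.880498,2030.158107
0.310000,2178.130527,2051.110603
0.315000,2157.832735,2031.996498
0.320000,2153.914719,2028.306964
0.325000,2143.001005,2018.029695
0.330000,2130.303265,2006.072437
0.335000,2098.470254,1976.095801
0.340000,2070.753615,1949.995486
0.345000,2047.238271,1927.851464
0.350000,2013.082383,1895.687411
0.355000,1986.210262,1870.382365
0.360000,1940.847615,1827.665088
0.365000,1897.597585,1786.937229
0.370000,1849.493608,1741.638485
0.375000,1808.416868,1702.957177
0.380000,1738.598460,1637.210301
0.385000,1681.919954,1583.837061
0.390000,1633.750298,1538.476467
0.395000,1561.706856,1470.634313
0.400000,1499.897472,1412.429407
0.405000,1421.635443,1338.731308
0.410000,1357.351622,1278.196265
0.415000,1287.760399,1212.663325
0.420000,1196.804740,1127.011840
0.425000,1125.260595,1059.639865
0.430000,1056.347794,994.745785
0.435000,992.239190,934.375740
0.440000,894.674636,842.500764
0.445000,807.277035,760.199843
0.450000,716.626134,674.835343
0.455000,643.298384,605.783777
0.460000,532.725666,501.659220
0.465000,469.464302,442.087008
0.470000,442.176228,416.390266
0.475000,440.491305,414.803601
0.480000,465.771772,438.609811
0.485000,423.095081,398.421856
0.490000,444.916980,418.971188
0.495000,445.729350,419.736184
0.500000,449.275590,423.075621
0.505000,430.856448,405.730611
0.510000,440.961260,415.246150
0.515000,431.802338,406.621341
0.520000,443.979176,418.088073
0.525000,446.859412,420.800345
0.530000,446.579592,420.536843
0.535000,443.352533,417.497974
0.540000,446.770598,420.716710
0.545000,446.694205,420.644772
0.550000,448.721320,422.553674
0.555000,445.339840,419.369388
0.560000,429.243618,404.211834
0.565000,437.862509,412.328106
0.570000,448.191677,422.054918
0.575000,437.011245,411.526485
0.580000,438.007455,412.464599
0.585000,446.124410,420.108206
0.590000,444.709962,418.776242
0.595000,453.072220,426.650847
0.600000,449.671957,423.448874
0.605000,441.241583,415.510126
0.610000,446.132401,420.115731
0.615000,419.664898,395.191708
0.620000,438.016533,412.473148
0.625000,443.802790,417.921973
0.630000,423.863309,399.145284
0.635000,442.244791,416.454831
0.640000,447.355453,421.267460
0.645000,454.328719,427.834072
0.650000,448.702251,422.535717
0.655000,461.889533,434.953969
0.660000,458.717633,431.967042
0.665000,430.565692,405.456811
0.670000,443.102904,417.262902
0.675000,443.724919,417.848644
0.680000,445.931511,419.926556
0.685000,440.016670,414.356645
0.690000,450.549204,424.274963
0.695000,451.747755,425.403619
0.700000,431.545906,406.379863
0.705000,453.531282,427.083139
0.710000,439.350612,413.729429
0.715000,454.518779,428.013049
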