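condition,tissue,gene,mean,sd,n
18,Brain,AFP1,33.485,3.920,3
18,Brain,CIRP,7.302,1.900,3
18,Brain,HMGB1,28.043,2.521,3
18,Brain,YB-1,14.051,0.647,3
18,Heart,AFP1,40.844,5.496,3
18,Heart,CIRP,12.447,2.165,3
18,Heart,HMGB1,16.091,1.397,3
18,Heart,YB-1,71.776,11.511,3
18,Intestine,AFP1,49.393,1.630,3
18,Intestine,CIRP,1.012,0.193,3
18,Intestine,HMGB1,1.002,0.093,3
18,Intestine,YB-1,4.633,0.599,3
18,Kidney,AFP1,138.641,18.764,3
18,Kidney,CIRP,6.787,0.517,3
18,Kidney,HMGB1,4.534,0.509,3
18,Kidney,YB-1,9.875,0.626,3
18,Liver,AFP1,57.209,29.476,3
18,Liver,CIRP,9.331,2.064,3
18,Liver,HMGB1,17.639,0.471,3
18,Liver,YB-1,53.148,8.477,3
18,Muscle,AFP1,194.620,36.069,3
18,Muscle,CIRP,15.674,0.434,3
18,Muscle,HMGB1,35.631,3.744,3
18,Muscle,YB-1,2710.596,483.487,3
18,Spleen,AFP1,91.363,9.527,3
18,Spleen,CIRP,3.982,0.129,3
18,Spleen,HMGB1,4.701,0.398,3
18,Spleen,YB-1,5.817,1.006,3
18,Skin,AFP1,145.049,11.767,3
18,Skin,CIRP,4.378,0.133,3
18,Skin,HMGB1,13.118,2.621,3
18,Skin,YB-1,75.281,5.565,3
18,Gonad,AFP1,1.025,0.286,3
18,Gonad,CIRP,2.733,0.260,3
18,Gonad,HMGB1,3.623,0.611,3
18,Gonad,YB-1,1.004,0.116,3
13,Brain,AFP1,155.071,10.673,3
13,Brain,CIRP,18.696,6.166,3
13,Brain,HMGB1,104.362,7.083,3
13,Brain,YB-1,29.748,6.091,3
13,Heart,AFP1,433.506,50.107,3
13,Heart,CIRP,12.978,2.688,3
13,Heart,HMGB1,19.716,2.299,3
13,Heart,YB-1,111.872,13.355,3
13,Intestine,AFP1,313.135,27.137,3
13,Intestine,CIRP,8.024,0.397,3
13,Intestine,HMGB1,13.614,0.943,3
13,Intestine,YB-1,32.797,4.534,3
13,Kidney,AFP1,273.210,43.607,3
13,Kidney,CIRP,19.429,1.665,3
13,Kidney,HMGB1,16.645,0.372,3
13,Kidney,YB-1,50.748,8.688,3
13,Liver,AFP1,365.993,88.821,3
13,Liver,CIRP,21.564,6.086,3
13,Liver,HMGB1,96.255,10.374,3
13,Liver,YB-1,68.932,7.887,3
13,Muscle,AFP1,387.966,27.999,3
13,Muscle,CIRP,16.792,1.359,3
13,Muscle,HMGB1,50.482,1.620,3
13,Muscle,YB-1,2000.654,86.534,3
13,Spleen,AFP1,388.093,49.514,3
13,Spleen,CIRP,5.310,0.349,3
13,Spleen,HMGB1,9.094,0.752,3
13,Spleen,YB-1,20.453,2.186,3
13,Skin,AFP1,441.387,55.797,3
13,Skin,CIRP,16.181,4.398,3
13,Skin,HMGB1,29.777,3.075,3
13,Skin,YB-1,66.961,8.481,3
13,Gonad,AFP1,4.213,0.471,3
13,Gonad,CIRP,2.295,0.246,3
13,Gonad,HMGB1,3.276,0.243,3
13,Gonad,YB-1,2.847,0.326,3
8,Brain,AFP1,684.934,160.236,3
8,Brain,CIRP,7.417,2.371,3
8,Brain,HMGB1,684.411,91.780,3
8,Brain,YB-1,2.077,0.299,3
8,Heart,AFP1,1499.415,286.439,3
8,Heart,CIRP,46.828,15.878,3
8,Heart,HMGB1,371.701,94.342,3
8,Heart,YB-1,26.619,3.228,3
8,Intestine,AFP1,1293.809,287.443,3
8,Intestine,CIRP,12.797,0.624,3
8,Intestine,HMGB1,70.688,10.000,3
8,Intestine,YB-1,5.130,3.108,3
8,Kidney,AFP1,2607.893,763.005,3
8,Kidney,CIRP,7.594,1.847,3
8,Kidney,HMGB1,69.846,7.990,3
8,Kidney,YB-1,1.232,1.149,3
8,Liver,AFP1,489.156,39.355,3
8,Liver,CIRP,5.962,1.397,3
8,Liver,HMGB1,89.556,13.502,3
8,Liver,YB-1,5.407,1.882,3
8,Muscle,AFP1,1811.152,690.646,3
8,Muscle,CIRP,40.804,11.521,3
8,Muscle,HMGB1,121.446,5.530,3
8,Muscle,YB-1,509.614,165.296,3
8,Spleen,AFP1,3179.010,33.714,3
8,Spleen,CIRP,12.285,4.973,3
8,Spleen,HMGB1,101.118,21.340,3
8,Spleen,YB-1,0.225,0.148,3
8,Skin,AFP1,893.144,54.822,3
8,Skin,CIRP,18.135,0.696,3
8,Skin,HMGB1,59.467,5.569,3
8,Skin,YB-1,66.343,14.264,3
8,Gonad,AFP1,449.5484,128.829,3
8,Gonad,CIRP,7.027,1.484,3
8,Gonad,HMGB1,35.308,4.753,3
8,Gonad,YB-1,1.818,0.545,3
5,Brain,AFP1,1066.966,58.627,3
5,Brain,CIRP,19.983,8.395,3
5,Brain,HMGB1,86.856,33.051,3
5,Brain,YB-1,35.377,7.525,3
5,Heart,AFP1,6293.382,351.457,3
5,Heart,CIRP,36.390,5.614,3
5,Heart,HMGB1,30.119,3.246,3
5,Heart,YB-1,181.004,50.614,3
5,Intestine,AFP1,1282.112,113.425,3
5,Intestine,CIRP,7.494,1.168,3
5,Intestine,HMGB1,3.419,0.285,3
5,Intestine,YB-1,19.524,4.315,3
5,Kidney,AFP1,2619.441,138.213,3
5,Kidney,CIRP,13.113,2.094,3
5,Kidney,HMGB1,7.102,0.812,3
5,Kidney,YB-1,16.438,4.316,3
5,Liver,AFP1,1794.711,268.371,3
5,Liver,CIRP,13.519,7.766,3
5,Liver,HMGB1,18.601,1.117,3
5,Liver,YB-1,28.098,1.714,3
5,Muscle,AFP1,6116.457,1378.037,3
5,Muscle,CIRP,89.788,57.712,3
5,Muscle,HMGB1,66.614,5.001,3
5,Muscle,YB-1,3514.809,638.609,3
5,Spleen,AFP1,3512.656,31.531,3
5,Spleen,CIRP,19.201,3.057,3
5,Spleen,HMGB1,15.677,1.745,3
5,Spleen,YB-1,29.009,2.606,3
5,Skin,AFP1,7400.707,868.984,3
5,Skin,CIRP,15.086,0.933,3
5,Skin,HMGB1,11.748,0.850,3
5,Skin,YB-1,151.941,40.267,3
5,Gonad,AFP1,2933.386,245.377,3
5,Gonad,CIRP,9.144,0.729,3
5,Gonad,HMGB1,22.158,3.001,3
5,Gonad,YB-1,21.180,4.578,3
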