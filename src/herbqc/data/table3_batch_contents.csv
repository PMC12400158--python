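batch,region,analyte,esm,qams,rd
HN1,HN,isochlorogenic acid C,3.567,,
HN1,HN,neochlorogenic acid,0.556,0.559,0.270
HN1,HN,chlorogenic acid,2.000,1.993,0.158
HN1,HN,cryptochlorogenic acid,0.671,0.674,0.223
HN1,HN,caffeic acid,0.131,0.132,0.699
HN1,HN,isochlorogenic acid B,1.997,1.984,0.307
HN1,HN,jaceosidin,0.592,0.598,0.448
HN1,HN,eupatilin,1.029,1.019,0.503
HN1,HN,total,6.975,6.960,0.112
HN2,HN,isochlorogenic acid C,3.843,,
HN2,HN,neochlorogenic acid,0.598,0.601,0.262
HN2,HN,chlorogenic acid,3.250,3.240,0.159
HN2,HN,cryptochlorogenic acid,0.570,0.572,0.217
HN2,HN,caffeic acid,0.108,0.109,0.708
HN2,HN,isochlorogenic acid B,1.596,1.587,0.306
HN2,HN,jaceosidin,0.464,0.468,0.448
HN2,HN,eupatilin,0.988,0.978,0.503
HN2,HN,total,7.574,7.556,0.123
HN3,HN,isochlorogenic acid C,3.715,,
HN3,HN,neochlorogenic acid,0.529,0.532,0.269
HN3,HN,chlorogenic acid,2.332,2.325,0.159
HN3,HN,cryptochlorogenic acid,0.574,0.577,0.222
HN3,HN,caffeic acid,0.142,0.144,0.717
HN3,HN,isochlorogenic acid B,1.750,1.739,0.307
HN3,HN,jaceosidin,0.686,0.692,0.446
HN3,HN,eupatilin,1.343,1.330,0.505
HN3,HN,total,7.357,7.339,0.123
HN4,HN,isochlorogenic acid C,2.283,,
HN4,HN,neochlorogenic acid,0.310,0.312,0.259
HN4,HN,chlorogenic acid,1.498,1.493,0.160
HN4,HN,cryptochlorogenic acid,0.357,0.358,0.219
HN4,HN,caffeic acid,0.095,0.096,0.721
HN4,HN,isochlorogenic acid B,0.864,0.859,0.308
HN4,HN,jaceosidin,0.479,0.483,0.443
HN4,HN,eupatilin,1.085,1.074,0.502
HN4,HN,total,4.688,4.676,0.130
HN5,HN,isochlorogenic acid C,4.237,,
HN5,HN,neochlorogenic acid,0.616,0.620,0.264
HN5,HN,chlorogenic acid,2.482,2.474,0.159
HN5,HN,cryptochlorogenic acid,0.577,0.579,0.223
HN5,HN,caffeic acid,0.116,0.118,0.704
HN5,HN,isochlorogenic acid B,2.492,2.477,0.307
HN5,HN,jaceosidin,0.549,0.554,0.445
HN5,HN,eupatilin,0.601,0.595,0.500
HN5,HN,total,7.433,7.416,0.113
HN6,HN,isochlorogenic acid C,2.764,,
HN6,HN,neochlorogenic acid,0.367,0.369,0.266
HN6,HN,chlorogenic acid,1.623,1.618,0.157
HN6,HN,cryptochlorogenic acid,0.354,0.356,0.213
HN6,HN,caffeic acid,0.049,0.049,0.693
HN6,HN,isochlorogenic acid B,1.614,1.604,0.304
HN6,HN,jaceosidin,0.525,0.530,0.445
HN6,HN,eupatilin,1.189,1.178,0.502
HN6,HN,total,5.721,5.703,0.157
HN7,HN,isochlorogenic acid C,4.977,,
HN7,HN,neochlorogenic acid,0.760,0.764,0.269
HN7,HN,chlorogenic acid,3.786,3.774,0.159
HN7,HN,cryptochlorogenic acid,0.576,0.578,0.223
HN7,HN,caffeic acid,0.089,0.090,0.693
HN7,HN,isochlorogenic acid B,3.621,3.599,0.306
HN7,HN,jaceosidin,0.610,0.615,0.441
HN7,HN,eupatilin,1.476,1.461,0.503
HN7,HN,total,10.918,10.882,0.163
HN8,HN,isochlorogenic acid C,1.571,,
HN8,HN,neochlorogenic acid,0.207,0.208,0.278
HN8,HN,chlorogenic acid,0.603,0.601,0.158
HN8,HN,cryptochlorogenic acid,0.278,0.279,0.228
HN8,HN,caffeic acid,0.134,0.136,0.725
HN8,HN,isochlorogenic acid B,0.668,0.664,0.306
HN8,HN,jaceosidin,0.441,0.444,0.449
HN8,HN,eupatilin,0.917,0.908,0.502
HN8,HN,total,3.247,3.240,0.105
HN9,HN,isochlorogenic acid C,3.974,,
HN9,HN,neochlorogenic acid,0.566,0.569,0.265
HN9,HN,chlorogenic acid,2.237,2.230,0.157
HN9,HN,cryptochlorogenic acid,0.594,0.597,0.225
HN9,HN,caffeic acid,0.127,0.129,0.698
HN9,HN,isochlorogenic acid B,1.823,1.812,0.305
HN9,HN,jaceosidin,0.462,0.466,0.442
HN9,HN,eupatilin,0.850,0.841,0.503
HN9,HN,total,6.658,6.643,0.113
HB1,HB,isochlorogenic acid C,2.577,,
HB1,HB,neochlorogenic acid,0.374,0.376,0.273
HB1,HB,chlorogenic acid,1.264,1.260,0.158
HB1,HB,cryptochlorogenic acid,0.337,0.339,0.221
HB1,HB,caffeic acid,0.043,0.044,0.754
HB1,HB,isochlorogenic acid B,1.571,1.561,0.305
HB1,HB,jaceosidin,0.446,0.450,0.445
HB1,HB,eupatilin,1.566,1.550,0.503
HB1,HB,total,5.601,5.580,0.188
HB2,HB,isochlorogenic acid C,2.170,,
HB2,HB,neochlorogenic acid,0.260,0.261,0.269
HB2,HB,chlorogenic acid,1.571,1.566,0.156
HB2,HB,cryptochlorogenic acid,0.281,0.282,0.225
HB2,HB,caffeic acid,0.070,0.071,0.736
HB2,HB,isochlorogenic acid B,1.253,1.245,0.306
HB2,HB,jaceosidin,0.527,0.531,0.442
HB2,HB,eupatilin,1.419,1.405,0.504
HB2,HB,total,5.380,5.361,0.171
HB3,HB,isochlorogenic acid C,2.943,,
HB3,HB,neochlorogenic acid,0.342,0.343,0.257
HB3,HB,chlorogenic acid,1.568,1.563,0.160
HB3,HB,cryptochlorogenic acid,0.331,0.333,0.216
HB3,HB,caffeic acid,0.066,0.067,0.694
HB3,HB,isochlorogenic acid B,2.449,2.434,0.306
HB3,HB,jaceosidin,0.569,0.575,0.451
HB3,HB,eupatilin,1.835,1.816,0.504
HB3,HB,total,7.159,7.130,0.204
HB4,HB,isochlorogenic acid C,3.024,,
HB4,HB,neochlorogenic acid,0.293,0.294,0.269
HB4,HB,chlorogenic acid,1.165,1.161,0.159
HB4,HB,cryptochlorogenic acid,0.335,0.337,0.220
HB4,HB,caffeic acid,0.086,0.087,0.684
HB4,HB,isochlorogenic acid B,2.598,2.582,0.308
HB4,HB,jaceosidin,0.883,0.891,0.443
HB4,HB,eupatilin,2.379,2.355,0.503
HB4,HB,total,7.738,7.707,0.203
HB5,HB,isochlorogenic acid C,3.152,,
HB5,HB,neochlorogenic acid,0.304,0.306,0.268
HB5,HB,chlorogenic acid,1.185,1.181,0.161
HB5,HB,cryptochlorogenic acid,0.355,0.357,0.218
HB5,HB,caffeic acid,0.084,0.085,0.717
HB5,HB,isochlorogenic acid B,1.688,1.678,0.306
HB5,HB,jaceosidin,0.526,0.531,0.447
HB5,HB,eupatilin,1.873,1.854,0.502
HB5,HB,total,6.016,5.992,0.197
HB6,HB,isochlorogenic acid C,1.453,,
HB6,HB,neochlorogenic acid,0.213,0.214,0.255
HB6,HB,chlorogenic acid,0.693,0.691,0.159
HB6,HB,cryptochlorogenic acid,0.183,0.184,0.214
HB6,HB,caffeic acid,0.038,0.038,0.779
HB6,HB,isochlorogenic acid B,0.998,0.991,0.307
HB6,HB,jaceosidin,0.943,0.951,0.446
HB6,HB,eupatilin,2.557,2.531,0.502
HB6,HB,total,5.624,5.601,0.204
HB7,HB,isochlorogenic acid C,2.033,,
HB7,HB,neochlorogenic acid,0.171,0.172,0.276
HB7,HB,chlorogenic acid,0.607,0.605,0.157
HB7,HB,cryptochlorogenic acid,0.221,0.221,0.225
HB7,HB,caffeic acid,0.032,0.032,0.640
HB7,HB,isochlorogenic acid B,1.202,1.195,0.307
HB7,HB,jaceosidin,0.576,0.581,0.446
HB7,HB,eupatilin,2.155,2.133,0.502
HB7,HB,total,4.962,4.939,0.235
HB8,HB,isochlorogenic acid C,2.113,,
HB8,HB,neochlorogenic acid,0.181,0.182,0.257
HB8,HB,chlorogenic acid,0.642,0.640,0.164
HB8,HB,cryptochlorogenic acid,0.243,0.244,0.213
HB8,HB,caffeic acid,0.032,0.033,0.707
HB8,HB,isochlorogenic acid B,1.372,1.364,0.309
HB8,HB,jaceosidin,0.592,0.597,0.449
HB8,HB,eupatilin,2.168,2.147,0.504
HB8,HB,total,5.231,5.206,0.235
HB9,HB,isochlorogenic acid C,4.758,,
HB9,HB,neochlorogenic acid,0.583,0.586,0.269
HB9,HB,chlorogenic acid,2.377,2.370,0.158
HB9,HB,cryptochlorogenic acid,0.607,0.610,0.217
HB9,HB,caffeic acid,0.085,0.086,0.681
HB9,HB,isochlorogenic acid B,2.780,2.763,0.306
HB9,HB,jaceosidin,0.796,0.803,0.450
HB9,HB,eupatilin,2.020,2.000,0.501
HB9,HB,total,9.248,9.217,0.165
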