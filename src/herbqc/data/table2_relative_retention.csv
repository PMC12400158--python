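factor,level,neochlorogenic acid,chlorogenic acid,cryptochlorogenic acid,caffeic acid,isochlorogenic acid B,jaceosidin,eupatilin
multi-point concentration correction,Linear-1,0.220,0.350,0.399,0.454,0.890,1.388,1.551
multi-point concentration correction,Linear-2,0.220,0.350,0.399,0.455,0.890,1.388,1.551
multi-point concentration correction,Linear-3,0.220,0.350,0.398,0.455,0.890,1.390,1.553
multi-point concentration correction,Linear-4,0.220,0.349,0.398,0.454,0.890,1.389,1.552
multi-point concentration correction,Linear-5,0.220,0.349,0.398,0.454,0.890,1.389,1.553
multi-point concentration correction,Linear-6,0.220,0.350,0.399,0.456,0.890,1.388,1.551
multi-point concentration correction,Linear-7,0.220,0.349,0.398,0.455,0.890,1.390,1.553
column batch,Batch-1,0.226,0.356,0.404,0.462,0.890,1.388,1.549
column batch,Batch-2,0.220,0.349,0.397,0.454,0.891,1.393,1.557
column batch,Batch-3,0.213,0.339,0.386,0.442,0.892,1.402,1.569
instrument,Waters H-Class,0.219,0.347,0.394,0.452,0.891,1.395,1.559
instrument,SHIMADZU LC-40Dxs,0.220,0.349,0.398,0.454,0.890,1.389,1.552
instrument,Thermo Vanquish,0.219,0.347,0.395,0.453,0.891,1.393,1.557
column temperature,28C,0.216,0.352,0.405,0.462,0.893,1.360,1.513
column temperature,30C,0.220,0.349,0.398,0.454,0.890,1.389,1.552
column temperature,32C,0.216,0.348,0.398,0.458,0.896,1.387,1.548
flow rate,0.38 mL/min,0.220,0.349,0.397,0.454,0.891,1.393,1.557
flow rate,0.40 mL/min,0.216,0.342,0.388,0.445,0.893,1.404,1.571
flow rate,0.42 mL/min,0.216,0.342,0.389,0.446,0.893,1.404,1.572
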