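factor,level,neochlorogenic acid,chlorogenic acid,cryptochlorogenic acid,caffeic acid,isochlorogenic acid B,jaceosidin,eupatilin
multi-point concentration correction,Linear-1,1.220,1.117,1.360,0.709,0.975,1.078,0.947
multi-point concentration correction,Linear-2,1.221,1.177,1.310,0.657,1.004,1.188,1.040
multi-point concentration correction,Linear-3,1.215,1.191,1.269,0.658,1.011,1.166,1.057
multi-point concentration correction,Linear-4,1.218,1.187,1.269,0.666,1.013,1.182,1.058
multi-point concentration correction,Linear-5,1.205,1.196,1.275,0.673,1.012,1.164,1.062
multi-point concentration correction,Linear-6,1.203,1.184,1.260,0.670,1.014,1.153,1.062
multi-point concentration correction,Linear-7,1.203,1.176,1.259,0.669,1.013,1.149,1.061
column batch,batch-1,1.236,1.187,1.277,0.672,1.010,1.171,1.064
column batch,batch-2,1.223,1.176,1.244,0.670,1.004,1.155,1.060
column batch,batch-3,1.234,1.183,1.276,0.665,1.008,1.197,1.067
instrument,Waters H-Class,1.283,1.184,1.270,0.659,1.004,1.162,1.061
instrument,SHIMADZU LC-40Dxs,1.218,1.187,1.269,0.666,1.013,1.182,1.058
instrument,Thermo Vanquish,1.272,1.183,1.267,0.671,0.997,1.155,1.058
column temperature,28C,1.182,1.175,1.235,0.667,1.002,1.126,1.033
column temperature,30C,1.218,1.187,1.269,0.666,1.013,1.182,1.058
column temperature,32C,1.215,1.174,1.271,0.664,1.013,1.176,1.068
flow rate,0.38 mL/min,1.223,1.176,1.244,0.670,1.004,1.155,1.060
flow rate,0.40 mL/min,1.209,1.168,1.273,0.649,1.004,1.205,1.055
flow rate,0.42 mL/min,1.216,1.181,1.276,0.649,1.006,1.181,1.068
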