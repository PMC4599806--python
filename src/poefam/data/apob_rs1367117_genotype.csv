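trait,study,n,beta,se,p
bmi,JPS,1246,0.689,0.310,0.0263
bmi,FHS,3666,-0.029,0.138,0.8329
bmi,FamHS,2228,0.329,0.173,0.0573
bmi,ERF,1968,0.306,0.168,0.0682
wc,JPS,1246,1.481,0.766,0.0534
wc,FHS,3659,-0.003,0.361,0.9925
wc,FamHS,2227,0.837,0.470,0.0748
wc,ERF,1965,0.670,0.488,0.1702
glucose,JPS,1077,-0.279,0.657,0.6715
glucose,FHS,3542,-0.127,0.205,0.5363
glucose,FamHS,2047,0.547,0.286,0.0560
glucose,ERF,1830,-0.131,0.428,0.7588
insulin,JPS,1112,0.030,0.036,0.4016
insulin,FHS,3229,0.008,0.013,0.5504
insulin,FamHS,2045,0.050,0.019,0.0076
insulin,ERF,1486,0.009,0.019,0.6154
ldl,JPS,1117,5.771,2.315,0.0128
ldl,FHS,3734,2.997,0.770,0.0001
ldl,FamHS,1925,0.696,1.079,0.5192
ldl,ERF,1802,6.501,1.401,0.0000035
hdl,JPS,1127,-0.671,0.946,0.4785
hdl,FHS,3771,-0.516,0.358,0.1501
hdl,FamHS,1967,-0.482,0.433,0.2660
hdl,ERF,1810,-0.963,0.545,0.0774
tc,JPS,1127,5.258,2.609,0.0441
tc,FHS,3778,2.632,0.867,0.0024
tc,FamHS,1967,0.664,1.197,0.5791
tc,ERF,1810,5.855,1.551,0.000161
tg,JPS,1127,0.013,0.036,0.7119
tg,FHS,3800,0.012,0.014,0.3829
tg,FamHS,2183,0.035,0.018,0.0537
tg,ERF,1810,0.024,0.020,0.2175
sbp,JPS,1231,1.253,0.759,0.0990
sbp,FHS,3793,0.251,0.314,0.4241
sbp,FamHS,1812,-0.055,0.445,0.9019
sbp,ERF,1751,0.022,0.653,0.9734
dbp,JPS,1231,1.428,0.580,0.0139
dbp,FHS,3791,-0.048,0.232,0.8347
dbp,FamHS,1812,-0.178,0.335,0.5954
dbp,ERF,1751,0.561,0.372,0.1314
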