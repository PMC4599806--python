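trait,origin,study,n,beta,se,p
bmi,maternal,JPS,1235,1.437,0.527,0.0065
bmi,maternal,FHS,2228,0.791,0.250,0.0015
bmi,maternal,FamHS,773,1.319,0.436,0.0025
bmi,maternal,ERF,622,-0.288,0.414,0.4863
bmi,paternal,JPS,1235,0.005,0.511,0.9927
bmi,paternal,FHS,2228,-0.219,0.242,0.3650
bmi,paternal,FamHS,773,-0.197,0.428,0.6455
bmi,paternal,ERF,622,0.340,0.413,0.4107
wc,maternal,JPS,1235,3.822,1.270,0.0027
wc,maternal,FHS,2225,2.231,0.649,0.0006
wc,maternal,FamHS,773,3.911,1.187,0.0010
wc,maternal,ERF,631,-3.037,3.110,0.3289
wc,paternal,JPS,1235,-0.646,1.249,0.6049
wc,paternal,FHS,2225,-0.244,0.632,0.6995
wc,paternal,FamHS,773,0.279,1.161,0.8101
wc,paternal,ERF,631,-0.834,3.084,0.7868
glucose,maternal,JPS,1068,0.342,1.160,0.7682
glucose,maternal,FHS,2153,1.315,0.382,0.0006
glucose,maternal,FamHS,761,0.036,0.653,0.9560
glucose,maternal,ERF,608,0.128,1.062,0.9041
glucose,paternal,JPS,1068,-0.757,0.984,0.4417
glucose,paternal,FHS,2153,-0.523,0.380,0.1694
glucose,paternal,FamHS,761,-1.070,0.681,0.1163
glucose,paternal,ERF,608,0.279,1.050,0.7905
insulin,maternal,JPS,1102,0.104,0.059,0.0790
insulin,maternal,FHS,1960,0.051,0.024,0.0356
insulin,maternal,FamHS,761,0.129,0.046,0.0049
insulin,maternal,ERF,510,0.012,0.044,0.7856
insulin,paternal,JPS,1102,-0.038,0.066,0.5585
insulin,paternal,FHS,1960,0.004,0.027,0.8823
insulin,paternal,FamHS,761,-0.006,0.049,0.9016
insulin,paternal,ERF,510,0.017,0.044,0.6999
ldl,maternal,JPS,1107,6.960,3.729,0.0622
ldl,maternal,FHS,2205,4.703,1.462,0.0013
ldl,maternal,FamHS,739,4.624,2.671,0.0834
ldl,maternal,ERF,586,3.333,1.332,0.0123
hdl,maternal,JPS,1117,-3.016,1.418,0.0337
hdl,maternal,FHS,2226,-1.048,0.670,0.1179
hdl,maternal,FamHS,752,-0.073,0.937,0.9379
hdl,maternal,ERF,589,0.441,0.539,0.4135
tc,maternal,JPS,1117,6.387,4.178,0.1266
tc,maternal,FHS,2230,4.918,1.660,0.0030
tc,maternal,FamHS,752,5.873,3.006,0.0507
tc,maternal,ERF,589,3.956,1.484,0.0077
tg,maternal,JPS,1117,0.097,0.061,0.1143
tg,maternal,FHS,2242,0.068,0.026,0.0083
tg,maternal,FamHS,752,0.017,0.048,0.7214
tg,maternal,ERF,590,0.019,0.041,0.6415
sbp,maternal,JPS,1220,1.120,1.145,0.3284
sbp,maternal,FHS,2234,1.927,0.585,0.0010
sbp,maternal,FamHS,733,1.376,0.905,0.1282
sbp,maternal,ERF,593,1.194,1.376,0.3856
dbp,maternal,JPS,1220,1.236,0.910,0.1743
dbp,maternal,FHS,2232,0.370,0.439,0.3990
dbp,maternal,FamHS,733,1.089,0.792,0.1692
dbp,maternal,ERF,593,1.495,0.908,0.0997
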