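SITE_ID,ASD_N,HC_N,AGE_MEAN,AGE_SD
Caltech,4,6,29.5,11.8
CMU,7,2,27.8,6.0
KKI,3,11,10.0,1.5
Leuven,14,12,22.8,3.6
MaxMum,15,24,26.3,11.0
NYU,30,69,15.7,6.6
OHSU,9,13,10.5,1.6
Olin,7,11,17.2,3.0
Pitt,22,21,19.0,6.9
Stanford,7,9,10.1,1.7
Trinity,17,24,16.9,3.4
UCLA,35,29,13.1,2.4
UM,9,16,16.3,3.8
USM,35,22,23.8,8.2
Yale,9,16,12.1,2.6
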