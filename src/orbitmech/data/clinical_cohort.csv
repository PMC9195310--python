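patient,side,volume_pre_cm3,volume_post_cm3,hertel_pre,hertel_post,dv_reported_cm3,keypoints,sex,age
1,left,47.7,57.8,21,18,10.1,kp2,f,57
2,right,36.7,39.1,16,10,3.1,kp1,m,66
3,right,32.3,35.9,27,17,3.6,kp1,f,55
4,right,34.0,38.6,28,22,4.6,kp1+kp2,f,48
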