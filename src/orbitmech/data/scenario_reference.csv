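scenario,family,area_cm2,V_pre_cm3,V_sim_cm3,dV_cm3,dV_rel_pct
l1,lateral,2.91,59.60,60.06,0.46,25.21
l2,lateral,5.55,59.60,60.52,0.92,50.85
l3,lateral,7.87,59.60,60.94,1.34,73.84
l4,lateral,9.28,59.60,61.41,1.81,100.00
f1,floor,3.31,59.60,62.46,2.86,46.99
f2,floor,6.04,59.60,64.01,4.41,72.49
f3,floor,7.58,59.60,64.87,5.27,86.58
f4,floor,9.69,59.60,65.68,6.08,100.00
l4+f4,two_wall,18.92,59.60,67.18,7.58,69.13
l4+f4+kp2,two_wall,19.36,59.60,70.56,10.97,100.00
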