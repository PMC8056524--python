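stratum,population,metric,roi,n,mean_pct,sd_pct
whole,all,SUVR,cortical,237,1.06,1.30
whole,noncarriers,SUVR,cortical,159,0.77,1.08
whole,carriers,SUVR,cortical,78,1.63,1.53
low,all,SUVR,cortical,194,0.80,1.18
low,noncarriers,SUVR,cortical,146,0.69,0.99
low,carriers,SUVR,cortical,48,1.15,1.56
intermediate,all,SUVR,cortical,20,2.83,0.93
intermediate,noncarriers,SUVR,cortical,5,2.81,0.69
intermediate,carriers,SUVR,cortical,15,2.84,1.02
high,all,SUVR,cortical,23,1.77,1.18
high,noncarriers,SUVR,cortical,8,2.37,1.34
high,carriers,SUVR,cortical,15,1.98,1.07
whole,all,SUVR,early,237,1.25,1.26
whole,noncarriers,SUVR,early,159,0.99,1.08
whole,carriers,SUVR,early,78,1.75,1.44
low,all,SUVR,early,194,1.02,1.16
low,noncarriers,SUVR,early,146,0.91,1.03
low,carriers,SUVR,early,48,1.34,1.44
intermediate,all,SUVR,early,20,2.87,1.02
intermediate,noncarriers,SUVR,early,5,2.74,0.90
intermediate,carriers,SUVR,early,15,2.90,1.08
high,all,SUVR,early,23,1.74,1.13
high,noncarriers,SUVR,early,8,1.36,1.17
high,carriers,SUVR,early,15,1.94,1.09
whole,all,DVR,cortical,237,0.75,1.11
whole,noncarriers,DVR,cortical,159,0.50,0.91
whole,carriers,DVR,cortical,78,1.25,1.30
low,all,DVR,cortical,194,0.49,0.96
low,noncarriers,DVR,cortical,146,0.40,0.82
low,carriers,DVR,cortical,48,0.75,1.29
intermediate,all,DVR,cortical,20,2.34,0.72
intermediate,noncarriers,DVR,cortical,5,2.53,0.43
intermediate,carriers,DVR,cortical,15,2.34,0.80
high,all,DVR,cortical,23,1.55,0.93
high,noncarriers,DVR,cortical,8,1.16,1.07
high,carriers,DVR,cortical,15,1.76,0.80
whole,all,DVR,early,237,0.94,1.08
whole,noncarriers,DVR,early,159,0.72,0.94
whole,carriers,DVR,early,78,1.34,1.22
low,all,DVR,early,194,0.71,0.97
low,noncarriers,DVR,early,146,0.63,0.87
low,carriers,DVR,early,48,0.94,1.19
intermediate,all,DVR,early,20,2.49,0.76
intermediate,noncarriers,DVR,early,5,2.55,0.71
intermediate,carriers,DVR,early,15,2.47,0.80
high,all,DVR,early,23,1.50,0.89
high,noncarriers,DVR,early,8,1.15,0.96
high,carriers,DVR,early,15,1.68,0.83
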