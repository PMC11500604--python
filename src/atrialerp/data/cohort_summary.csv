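patient,sex,chamber,volume_ml,area_cm2,lva_pct,erp_mean_ms,erp_sd_ms,n_measurements,diagnosis
P1,F,LA,270.1,267.4,45.49,222.0,11.0,5,PAF
P2,M,RA,221.4,200.7,25.78,222.5,14.9,8,AFl
P3,F,LA,175.9,179.8,46.04,232.0,16.4,7,PAF
P4,M,LA,175.6,187.4,74.02,236.3,21.3,5,PeAF
P5,M,LA,86.9,120.0,47.36,284.0,20.7,5,PeAF
P6,F,LA,95.2,121.2,28.85,286.0,13.4,4,PAF
P7,M,LA,106.8,136.9,32.35,295.0,20.8,6,PAF
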