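nominal_pg_per_mg,scope,n,mean_pg_per_mg,sd_pg_per_mg,rsd_percent_printed,bias_percent_printed
20,intra_day,3,19.9,3.1,15,0.5
30,intra_day,3,31.8,2.2,10,3.2
60,intra_day,3,65.9,5.2,9,5.9
20,inter_day,9,18.4,2.6,14,8.2
30,inter_day,9,27.8,2.7,10,7.3
60,inter_day,9,56.6,4.3,8,5.6
6,loq_intra_day,6,5.66,,11,6
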