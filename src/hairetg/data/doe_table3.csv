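block,run_label,a,b,c,response_pg_per_mg
subject1,0,-1,-1,-1,81.8
subject1,a,1,-1,-1,74.9
subject1,b,-1,1,-1,130.6
subject1,ab,1,1,-1,168.0
subject1,c,-1,-1,1,180.8
subject1,ac,1,-1,1,181.8
subject1,bc,-1,1,1,188.9
subject1,abc,1,1,1,171.6
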