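quadrat,site,zone,rockpool_cover_pct,sp001,sp002,sp003,sp004,sp005,sp006,sp007,sp008
q1,synthfix,low,0.0,0.0,0.0,0.0,46.1,0.0,58.6,7.5,47.6
q2,synthfix,low,12.5,5.7,0.0,15.2,34.2,27.7,0.0,0.0,49.7
q3,synthfix,mid,0.0,4.5,29.1,10.9,41.6,0.0,47.1,0.0,13.3
q4,synthfix,mid,12.5,0.0,40.8,27.4,0.0,50.3,9.5,29.6,15.2
q5,synthfix,upper,0.0,18.7,2.4,41.6,0.0,0.0,13.6,10.1,0.0
q6,synthfix,upper,12.5,0.0,0.0,10.1,29.3,34.8,40.8,46.4,8.6
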