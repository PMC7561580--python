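quadrat,species,cover,site,zone,rockpool_cover_pct
q1,sp004,46.1,synthfix,low,0.0
q1,sp006,58.6,synthfix,low,0.0
q1,sp007,7.5,synthfix,low,0.0
q1,sp008,47.6,synthfix,low,0.0
q2,sp001,5.7,synthfix,low,12.5
q2,sp003,15.2,synthfix,low,12.5
q2,sp004,34.2,synthfix,low,12.5
q2,sp005,27.7,synthfix,low,12.5
q2,sp008,49.7,synthfix,low,12.5
q3,sp001,4.5,synthfix,mid,0.0
q3,sp002,29.1,synthfix,mid,0.0
q3,sp003,10.9,synthfix,mid,0.0
q3,sp004,41.6,synthfix,mid,0.0
q3,sp006,47.1,synthfix,mid,0.0
q3,sp008,13.3,synthfix,mid,0.0
q4,sp002,40.8,synthfix,mid,12.5
q4,sp003,27.4,synthfix,mid,12.5
q4,sp005,50.3,synthfix,mid,12.5
q4,sp006,9.5,synthfix,mid,12.5
q4,sp007,29.6,synthfix,mid,12.5
q4,sp008,15.2,synthfix,mid,12.5
q5,sp001,18.7,synthfix,upper,0.0
q5,sp002,2.4,synthfix,upper,0.0
q5,sp003,41.6,synthfix,upper,0.0
q5,sp006,13.6,synthfix,upper,0.0
q5,sp007,10.1,synthfix,upper,0.0
q6,sp003,10.1,synthfix,upper,12.5
q6,sp004,29.3,synthfix,upper,12.5
q6,sp005,34.8,synthfix,upper,12.5
q6,sp006,40.8,synthfix,upper,12.5
q6,sp007,46.4,synthfix,upper,12.5
q6,sp008,8.6,synthfix,upper,12.5
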