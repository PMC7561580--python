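species,sta,sa_v,thickness,tdmc,c_n,length,pneumatocysts,branching_order,sa_p
sp001,63.8028,12.6964,0.808,0.2979,9.3726,2.7194,0.0,0.0,4.9871
sp002,49.3324,12.3169,0.9508,0.284,20.3834,30.8713,0.0,3.0,2.116
sp003,67.1564,13.6486,0.8264,0.201,14.1608,5.0615,1.0,3.0,3.5408
sp004,35.4939,13.7171,0.8496,0.2421,20.8413,15.3852,0.0,9.0,1.8937
sp005,33.1893,10.2254,1.0127,0.3338,21.6191,4.3164,0.0,0.0,11.0317
sp006,90.6156,37.0425,0.2311,0.2034,15.3134,12.4444,0.0,3.0,4.2316
sp007,86.0694,27.625,0.4307,0.2472,9.6203,7.2639,0.0,0.0,4.1398
sp008,40.1214,41.1548,0.2616,0.2797,9.5851,7.1542,0.0,1.0,7.2001
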