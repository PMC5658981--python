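option,os,hrqol,pfs,g4ae,atc_l4,phase3,mkt_auth,posology,med_costs
aflibercept_folfiri,13.5,0.78,6.9,21,1st,18,3,"Many hours, every 2 weeks",6738
cetuximab,10,0.78,4.1,5,1st,19,1,"1 hour, every week",4589
panitumumab,10.4,0.78,4.4,7,2nd or later,7,0,"≤1 hour, every 2 weeks",1940
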