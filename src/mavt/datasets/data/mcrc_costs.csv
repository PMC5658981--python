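option,drug_cost,admin_cost,total_cost
aflibercept_folfiri,17750,11630,29400
cetuximab,12824,5191,18000
panitumumab,23643,3374,27000
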