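tariff_name,term,value
uk_tto,full_health,1.0
uk_tto,any_problem,0.081
uk_tto,MO2,0.069
uk_tto,MO3,0.314
uk_tto,SC2,0.104
uk_tto,SC3,0.214
uk_tto,UA2,0.036
uk_tto,UA3,0.094
uk_tto,PD2,0.123
uk_tto,PD3,0.386
uk_tto,AD2,0.071
uk_tto,AD3,0.236
uk_tto,N3,0.269
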