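country,n_farms,cycle_index,n_farms_with_amu,median_days,mean_days
NL,13,1,3,5,5.3
NL,13,2,7,3,3.8
NL,13,3,8,3,3.5
NL,13,4,4,4,5.6
CY,7,1,6,11,10.7
CY,7,2,6,4.5,5.8
CY,7,3,3,7,6.0
CY,7,4,2,6,6.0
GR,15,1,15,7,6.4
GR,15,2,15,5,4.6
GR,15,3,15,6,6.0
GR,15,4,15,6,5.9
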