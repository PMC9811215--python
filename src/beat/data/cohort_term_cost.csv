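term,cost,planned,realized_pct
short,low,222,53
short,medium,44,43
short,high,0,
medium,low,88,51
medium,medium,94,12
medium,high,33,21
long,low,0,
long,medium,44,20
long,high,111,1
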