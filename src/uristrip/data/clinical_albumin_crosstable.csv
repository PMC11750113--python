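# Albumin screening 2x2 at the 30 mg/L microalbuminuria threshold
# (program judgment vs analyzer), 42 specimens.
cell,count
tp,13
fp,12
fn,0
tn,17
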