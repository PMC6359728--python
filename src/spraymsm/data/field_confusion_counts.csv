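land,location,tp,fp,fn,tn
cropland,L1,74,21,16,79
cropland,L2,38,11,18,31
cropland,L3,56,0,31,25
orchard,L1,35,9,13,31
orchard,L2,41,2,10,33
orchard,L3,37,18,15,40
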