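garment,clo
t_shirt,0.08
short_sleeve_shirt,0.19
long_sleeve_shirt,0.25
blouse,0.15
sweater,0.28
thick_sweater,0.35
vest,0.13
jacket,0.36
coat,0.60
trousers,0.25
thick_trousers,0.28
skirt,0.18
dress,0.33
shorts,0.08
underwear,0.04
bra,0.01
socks,0.02
thick_socks,0.05
shoes,0.02
boots,0.10
scarf,0.05
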