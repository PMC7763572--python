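metabolite,center_ppm,rel_height,width_ppm
isoleucine,0.90,1.0,0.01
leucine,0.98,1.0,0.01
valine,1.04,1.0,0.01
isopropanol,1.13,1.0,0.01
ethanol,1.19,1.0,0.01
butyrate,1.26,1.0,0.01
lactate,1.33,1.0,0.01
alanine,1.48,1.0,0.01
isocaproate,1.56,1.0,0.01
acetate,1.92,1.0,0.01
propionate,2.05,1.0,0.01
isovalerate,2.14,1.0,0.01
acetoin,2.22,1.0,0.01
pyruvate,2.31,1.0,0.01
succinate,2.41,1.0,0.01
methylamine,2.55,1.0,0.01
sarcosine,2.73,1.0,0.01
aspartate,2.88,1.0,0.01
creatine,3.03,1.0,0.01
choline,3.20,1.0,0.01
taurine,3.28,1.0,0.01
methanol,3.36,1.0,0.01
glucose,3.43,1.0,0.01
glycine,3.56,1.0,0.01
galactose,3.65,1.0,0.01
proline,3.78,1.0,0.01
tyrosine,6.88,1.0,0.01
phenylalanine,7.33,1.0,0.01
uracil,7.54,1.0,0.01
hypoxanthine,8.19,1.0,0.01
formate,8.46,1.0,0.01
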