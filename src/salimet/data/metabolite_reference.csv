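metabolite,mean_B,sd_B,mean_AT,sd_AT,mean_HI,sd_HI,p_kruskal_wallis,p_wilcoxon_paired,p_mann_whitney
alanine,2318.68,2156.2,835.16,400.38,731.26,324.31,0.099,0.052,0.740
acetate,82191.52,63733.79,119495.6,38614.2,180849.4,63915.1,0.002,0.176,0.004
propionate,10620.21,8802.07,18185.02,14457.12,16615.03,9427.33,0.327,0.204,0.880
glycine,4896.88,3390.89,4134.86,1717.69,3252.59,1542.33,0.446,0.470,0.347
butyrate,460.82,573.65,811.82,726.82,540.03,563.16,0.187,0.151,0.288
taurine,1551.22,886.83,1053.22,447.67,946.69,452.63,0.089,0.151,0.782
ethanol,170.8,126.63,294,248.31,529.93,325.07,0.003,0.204,0.037
proline,389.02,498.62,363.87,218.22,176,122.96,0.076,0.910,0.016
succinate,1270.54,2849.59,1783.53,1496.6,3052.11,3424.66,0.022,0.129,0.651
leucine,1639.75,1527.77,689.34,441.56,697.94,171.73,0.035,0.042,0.230
valine,1077.09,1001.68,305.23,335.29,551.16,245.92,0.005,0.001,0.009
isovalerate,479.45,450.54,536.68,453.33,438.91,235.4,0.868,0.910,0.805
isocaproate,148.83,168.95,222.04,144.81,315.28,274.43,0.162,0.151,0.566
acetoin,201.97,167.61,210.34,165.32,510.06,283.17,0.002,0.910,0.002
tyrosine,509.97,456.14,307.53,210.88,270.99,232.4,0.472,0.129,0.442
methylamine,298.9,354.4,169.15,73.67,274.34,96.61,0.064,0.301,0.006
phenylalanine,1177.75,1088.23,479.24,169.59,547.29,188.64,0.036,0.034,0.566
isoleucine,636.39,714.79,143.31,98.65,193.49,79.1,0.012,0.007,0.104
galactose,80.22,93.82,140.2,166.6,139.57,285.92,0.738,0.176,0.644
lactate,3359.7,2674.72,5413.35,5361.44,1349.14,1394.03,0.019,0.470,0.011
aspartate,155.65,104.89,106.12,94.69,58.25,37.36,0.068,0.129,0.185
creatine,295.84,307.4,226.62,413.65,494.94,558.86,0.080,0.301,0.021
choline,848.12,834.16,879.44,908.5,1372.24,526.06,0.041,0.970,0.023
methanol,564.8,343,1452.51,2117.43,637.3,739.04,0.134,0.052,0.079
pyruvate,470.4,460.62,961.51,731.33,1077.92,1722.88,0.192,0.129,0.288
formate,776.5,1976.83,1656.13,2726.19,513.89,799.4,0.206,0.016,0.176
glucose,161.94,188.36,74.34,83.34,70.2,97.73,0.365,0.380,0.667
sarcosine,253.02,279.33,244.6,257.13,202.9,75.21,0.980,0.970,0.878
hypoxanthine,167,303.72,33.43,20.06,30.65,20.27,0.010,0.012,0.740
uracil,383.07,622.49,61.67,49.7,74.81,65.7,0.030,0.005,1.000
isopropanol,181.78,134.02,293.53,221.85,406.78,247.21,0.048,0.307,0.260
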