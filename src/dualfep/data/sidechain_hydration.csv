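mimic,experimental,x_to_me,x_to_me_sem,me_to_x,me_to_x_sem,average,hysteresis,midpoint,midpoint_sem,charged
propane,-0.05,0.20,0.08,-0.19,0.19,0.20,0.01,0.08,0.12,0
isobutane,-0.34,-0.27,0.16,0.22,0.09,-0.25,0.05,-0.04,0.12,0
1-butane,-0.21,0.02,0.25,-0.33,0.11,0.16,0.35,-0.06,0.11,0
ethanol,6.82,7.05,0.15,-6.97,0.11,7.01,0.08,6.75,0.14,0
methanol,7.00,6.69,0.07,-6.69,0.07,6.69,0.00,6.62,0.08,0
methanethiol,3.18,2.01,0.05,-1.61,0.09,1.81,0.40,1.78,0.05,0
methylsulfanylethane,3.42,2.68,0.08,-2.39,0.37,2.54,0.29,2.06,0.11,0
acetamide,11.62,10.91,0.16,-10.89,0.08,10.90,0.02,10.93,0.10,0
propionamide,11.32,11.02,0.31,-11.09,0.14,11.06,0.07,11.29,0.15,0
toluene,2.70,2.56,0.48,-1.96,0.63,2.26,0.60,2.66,0.35,0
p-cresol,8.05,8.16,0.44,-7.20,0.12,7.68,0.96,7.74,0.48,0
4-methylimidazole-NdH,12.21,9.86,0.09,-8.35,0.96,9.11,1.51,10.22,0.13,0
4-methylimidazole-NeH,12.21,11.13,0.15,-10.85,0.17,10.99,0.28,10.68,0.34,0
3-methylindole,7.82,6.25,0.37,-5.25,0.13,5.75,1.00,7.41,0.52,0
n-propylguanidine,12.86,16.43,0.44,-15.47,0.53,15.95,0.96,16.99,0.29,0
acetic-acid-COOH,8.64,8.16,0.08,-7.84,0.09,8.00,0.32,8.07,0.11,0
propionic-acid-COOH,8.41,11.44,0.17,-11.41,0.15,11.43,0.03,11.98,0.23,0
butan-1-amine-NH2,6.32,5.52,0.22,-4.37,0.34,4.95,1.15,4.88,0.38,0
n-propylguanidinium,69.15,68.17,0.51,-67.05,0.35,67.61,1.13,67.33,0.71,1
acetate,79.52,82.64,0.10,-82.21,0.22,82.42,0.43,82.71,0.07,1
propionate,78.04,82.28,0.21,-82.63,0.31,82.45,0.35,82.37,0.13,1
butan-1-aminium,73.07,77.71,0.48,-78.49,0.16,78.10,0.78,78.39,0.22,1
4-methylimidazolium,64.23,67.75,0.19,-67.77,0.18,67.75,0.02,67.42,0.20,1
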