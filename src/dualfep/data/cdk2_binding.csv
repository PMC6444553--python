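ligand,experimental,fepplus_opls2005,fepplus_opls2005_sem,fepplus_opls3,fepplus_opls3_sem,opls2005,opls2005_sem,amber,amber_sem,charmm,charmm_sem
1h1q,-8.18,-8.15,0.00,-7.56,0.00,,,,,,
1h1r,-7.67,-8.52,0.26,-8.61,0.17,-8.04,0.11,-7.52,0.31,-9.75,0.45
1h1s,-11.25,-10.66,0.40,-10.14,0.56,-10.90,0.28,-11.07,0.41,-12.60,0.72
1oi9,-9.74,-9.95,0.32,-9.66,0.22,-9.88,0.16,-10.40,0.24,-9.35,0.49
1oiu,-9.08,-10.10,0.24,-9.50,0.47,-9.89,0.26,-10.81,0.74,-11.26,0.63
1oiy,-9.79,-8.97,0.29,-8.94,0.39,-10.10,0.23,-10.82,0.48,-11.13,0.52
17,-7.04,-8.56,0.19,-8.79,0.13,-7.99,0.11,-9.14,0.51,-10.63,0.33
20,-8.72,-8.52,0.33,-7.96,0.28,-8.70,0.18,-8.60,0.23,-8.65,0.37
21,-7.83,-8.50,0.27,-8.70,0.15,-7.54,0.15,-7.07,0.35,-11.11,0.39
22,-7.76,-8.58,0.23,-9.00,0.18,-7.74,0.15,-6.68,0.51,-9.66,0.47
26,-8.43,-9.44,0.33,-8.68,0.39,-9.57,0.14,-9.42,0.44,-10.31,0.59
28,-11.11,-9.90,0.49,-10.31,0.49,-13.47,1.10,-5.45,0.93,-11.54,0.89
29,-9.88,-9.53,0.47,-9.32,0.61,-13.59,0.99,-11.44,1.18,-11.55,1.21
30,-9.81,-8.92,0.38,-9.13,0.48,-10.87,0.60,-11.48,0.77,-10.92,0.50
31,-9.54,-8.19,0.41,-9.03,0.46,-8.75,0.19,-9.68,0.48,-10.83,0.91
32,-9.75,-9.26,0.47,-10.27,0.49,-8.48,0.84,-9.77,0.65,-11.92,0.93
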