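ligand,r_group,experimental,fepplus,fepplus_sem,ddg,ddg_sem
11,H,,,,,
25a,CH3,0.25,0.53,0.04,0.74,0.34
25b,(CH2)3CH3,-1.15,-0.34,0.10,-0.96,0.81
25c,(CH2)4CH3,-1.56,-0.56,0.09,-0.93,0.86
25d,(CH2)2Ph,-1.35,-0.69,0.11,-0.75,0.95
25e,CH(CH3)2,1.39,0.88,0.09,2.46,0.99
25f,(CH2)2CH3,0.35,0.23,0.07,2.17,1.07
32,H,0.06,1.24,0.18,0.67,0.22
41,CH3,0.56,3.08,0.16,0.98,0.33
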