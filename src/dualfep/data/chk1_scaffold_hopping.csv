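ligand,experimental,fepplus,fepplus_sem,ddg,ddg_sem
17>1,0.02,-0.85,0.09,-0.39,0.41
1>19,1.15,0.93,0.08,0.41,0.48
1>20,0.49,0.60,0.03,0.30,0.30
17>20,0.51,0.06,0.10,0.32,0.56
19>21,-0.59,0.03,0.15,-0.14,1.17
20>21,0.07,0.08,0.16,-0.15,0.27
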