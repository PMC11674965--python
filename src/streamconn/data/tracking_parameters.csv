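subsystem,roi_a,roi_b,min_length_mm,max_length_mm,angular_threshold_deg,qa_threshold
DVS,L SOG,L IPL,10,100,60,0.01
DVS,L SOG,L SPL,10,300,70,0.01
DVS,R SOG,R IPL,10,100,75,0.005
DVS,R SOG,R SPL,10,150,70,0.01
VVS,L IOG,L ITG,10,20,50,0.01
VVS,L IOG,L FG,10,35,50,0.01
VVS,R IOG,R ITG,10,20,50,0.01
VVS,R IOG,R FG,10,35,50,0.01
VS,L Calc,L IOG,10,70,65,0.01
VS,L Calc,L SOG,5,20,50,0.01
VS,R Calc,R IOG,10,80,65,0.01
VS,R Calc,R SOG,10,30,50,0.01
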