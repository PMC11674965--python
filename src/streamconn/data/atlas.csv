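name,x,y,z,subsystems
L SOG,-26,-73,23,DVS;VS
L IPL,-24,-52,52,DVS
L SPL,-30,-46,66,DVS
R SOG,23,-91,26,DVS;VS
R IPL,24,-48,42,DVS
R SPL,20,-68,62,DVS
L IOG,-42,-64,-12,VVS;VS
L ITG,-44,-50,-15,VVS
L FG,-34,-48,-16,VVS
R IOG,40,-64,-12,VVS;VS
R ITG,48,-60,-12,VVS
R FG,40,-52,-16,VVS
L Calc,-8,-86,6,VS
R Calc,8,-86,6,VS
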