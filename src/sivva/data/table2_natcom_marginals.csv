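entity,level,ES,VU,CV
barrier islands,SC1,0.86,0.50,0.49
barrier islands,SC2,0.84,0.48,0.47
barrier islands,SC3,0.84,0.54,0.47
barrier islands,LM,0.72,0.39,0.61
barrier islands,WGCP,0.89,0.48,0.72
barrier islands,MAP,0.96,0.57,0.52
barrier islands,SCP,0.76,0.47,0.33
barrier islands,CFCP,0.86,0.49,0.44
barrier islands,SFCP,,,
tidal emergent marsh,SC1,0.78,0.59,0.64
tidal emergent marsh,SC2,0.78,0.63,0.67
tidal emergent marsh,SC3,0.79,0.67,0.70
tidal emergent marsh,LM,0.69,0.53,0.47
tidal emergent marsh,WGCP,0.72,0.58,0.50
tidal emergent marsh,MAP,0.86,0.65,0.56
tidal emergent marsh,SCP,0.75,0.54,0.32
tidal emergent marsh,CFCP,0.78,0.48,0.50
tidal emergent marsh,SFCP,1.00,0.80,0.67
mangrove,SC1,0.66,0.58,0.47
mangrove,SC2,0.66,0.58,0.47
mangrove,SC3,0.66,0.58,0.47
mangrove,LM,0.67,0.72,0.50
mangrove,WGCP,0.64,0.54,0.42
mangrove,MAP,0.63,0.54,0.42
mangrove,SCP,0.64,0.48,0.38
mangrove,CFCP,0.72,0.69,0.42
mangrove,SFCP,0.69,0.60,0.59
oyster reef,SC1,0.83,0.52,0.44
oyster reef,SC2,0.86,0.55,0.44
oyster reef,SC3,0.86,0.56,0.44
oyster reef,LM,0.78,0.70,0.44
oyster reef,WGCP,0.87,0.59,0.44
oyster reef,MAP,0.92,0.64,0.44
oyster reef,SCP,0.78,0.44,0.43
oyster reef,CFCP,0.89,0.31,0.44
oyster reef,SFCP,0.67,0.26,0.44
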