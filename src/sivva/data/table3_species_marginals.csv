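entity,level,V,AC,CV,IA
eastern oyster,SC1,0.59,0.44,0.53,0.72
eastern oyster,SC2,0.62,0.46,0.52,0.73
eastern oyster,SC3,0.67,0.47,0.52,0.73
eastern oyster,LM,0.55,0.42,0.57,0.63
eastern oyster,MAP,0.53,0.40,0.57,0.50
eastern oyster,WGCP,0.59,0.46,0.55,0.69
eastern oyster,SCP,0.64,0.45,0.52,0.80
eastern oyster,CFCP,0.66,0.43,0.50,0.78
eastern oyster,SFCP,0.49,0.41,0.50,0.78
red drum,SC1,0.52,0.31,0.49,0.75
red drum,SC2,0.60,0.31,0.43,0.75
red drum,SC3,0.63,0.33,0.43,0.75
red drum,LM,0.52,0.21,0.45,0.89
red drum,MAP,0.58,0.46,0.53,0.78
red drum,WGCP,0.55,0.33,0.49,0.83
red drum,SFCP,0.46,0.21,0.47,0.67
red drum,CFCP,0.52,0.21,0.47,0.67
red drum,SCP,0.46,0.38,0.53,0.58
mottled duck,SC1,0.58,0.38,0.46,0.51
mottled duck,SC2,0.58,0.38,0.37,0.51
mottled duck,SC3,0.63,0.40,0.37,0.51
mottled duck,LM,0.49,0.45,0.44,0.54
mottled duck,MAP,0.57,0.38,0.43,0.53
mottled duck,WGCP,0.56,0.45,0.44,0.54
mottled duck,SFCP,0.58,0.29,0.50,0.42
mottled duck,CFCP,0.60,0.29,0.50,0.42
mottled duck,SCP,0.69,0.43,0.50,0.61
spotted seatrout,SC1,0.47,0.39,0.44,0.62
spotted seatrout,SC2,0.48,0.39,0.44,0.62
spotted seatrout,SC3,0.50,0.39,0.44,0.62
spotted seatrout,LM,0.42,0.31,0.40,0.50
spotted seatrout,MAP,0.59,0.41,0.45,0.56
spotted seatrout,WGCP,0.59,0.41,0.45,0.56
spotted seatrout,SFCP,0.35,0.40,0.43,0.75
spotted seatrout,CFCP,0.40,0.40,0.43,0.75
spotted seatrout,SCP,0.46,0.42,0.50,0.58
American oystercatcher,SC1,0.64,0.56,0.34,0.52
American oystercatcher,SC2,0.66,0.56,0.32,0.53
American oystercatcher,SC3,0.70,0.57,0.32,0.53
American oystercatcher,LM,0.48,0.55,0.32,0.50
American oystercatcher,MAP,0.60,0.43,0.31,0.59
American oystercatcher,WGCP,0.54,0.57,0.33,0.51
American oystercatcher,SFCP,0.84,0.75,0.35,0.58
American oystercatcher,CFCP,0.79,0.65,0.35,0.53
American oystercatcher,SCP,0.72,0.53,0.36,0.47
clapper rail,SC1,0.59,0.45,0.34,0.57
clapper rail,SC2,0.58,0.45,0.36,0.55
clapper rail,SC3,0.61,0.45,0.36,0.55
clapper rail,LM,0.67,0.54,0.35,0.63
clapper rail,MAP,0.66,0.42,0.32,0.50
clapper rail,WGCP,0.57,0.54,0.35,0.63
clapper rail,SFCP,0.72,0.56,0.47,0.69
clapper rail,CFCP,0.51,0.38,0.35,0.54
clapper rail,SCP,0.54,0.43,0.32,0.56
blue crab,SC1,0.40,0.21,0.46,0.56
blue crab,SC2,0.41,0.21,0.46,0.56
blue crab,SC3,0.39,0.21,0.46,0.56
blue crab,LM,0.41,0.20,0.48,0.47
blue crab,MAP,0.39,0.27,0.40,0.73
blue crab,WGCP,0.40,0.20,0.48,0.47
blue crab,SFCP,0.40,0.17,0.50,0.58
blue crab,CFCP,0.45,0.17,0.50,0.58
blue crab,SCP,0.32,0.19,0.43,0.50
roseate spoonbill,SC1,0.63,0.53,0.44,0.52
roseate spoonbill,SC2,0.67,0.56,0.47,0.50
roseate spoonbill,SC3,0.71,0.57,0.47,0.50
roseate spoonbill,LM,0.49,0.54,0.42,0.60
roseate spoonbill,MAP,0.64,0.36,0.40,0.38
roseate spoonbill,WGCP,0.58,0.45,0.41,0.49
roseate spoonbill,SFCP,0.56,0.47,0.46,0.55
roseate spoonbill,CFCP,0.76,0.60,0.46,0.57
roseate spoonbill,SCP,0.72,0.77,0.43,0.53
black skimmer,SC1,0.68,0.48,0.43,0.46
black skimmer,SC2,0.70,0.47,0.40,0.45
black skimmer,SC3,0.73,0.48,0.40,0.45
black skimmer,LM,0.60,0.58,0.40,0.50
black skimmer,MAP,0.74,0.38,0.43,0.45
black skimmer,WGCP,0.67,0.44,0.43,0.48
black skimmer,SFCP,0.71,0.56,0.45,0.44
black skimmer,CFCP,0.68,0.46,0.43,0.42
black skimmer,SCP,0.66,0.60,0.43,0.42
Wilson's plover,SC1,0.66,0.60,0.37,0.46
Wilson's plover,SC2,0.71,0.54,0.37,0.45
Wilson's plover,SC3,0.74,0.56,0.36,0.46
Wilson's plover,LM,0.55,0.61,0.37,0.45
Wilson's plover,MAP,0.71,0.45,0.38,0.47
Wilson's plover,WGCP,0.64,0.51,0.38,0.48
Wilson's plover,SFCP,0.64,0.92,0.32,0.47
Wilson's plover,CFCP,0.64,0.92,0.32,0.47
Wilson's plover,SCP,0.85,0.55,0.40,0.39
Kemp's ridley sea turtle,SC1,0.62,0.76,0.66,0.54
Kemp's ridley sea turtle,SC2,0.70,0.77,0.61,0.54
Kemp's ridley sea turtle,SC3,0.70,0.75,0.57,0.56
Kemp's ridley sea turtle,LM,0.50,0.71,0.70,0.64
Kemp's ridley sea turtle,MAP,,,,
Kemp's ridley sea turtle,WGCP,0.71,0.85,0.58,0.53
Kemp's ridley sea turtle,SFCP,,,,
Kemp's ridley sea turtle,CFCP,,,,
Kemp's ridley sea turtle,SCP,0.70,0.76,0.66,0.45
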