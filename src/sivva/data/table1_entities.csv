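entity,entity_type,community,n_assessments,taxon_group
mangrove,natcom,,33,
tidal emergent marsh,natcom,,25,
oyster reef,natcom,,28,
barrier islands,natcom,,31,
roseate spoonbill,species,mangrove,21,bird
blue crab,species,tidal emergent marsh,27,invertebrate
clapper rail,species,tidal emergent marsh,25,bird
mottled duck,species,tidal emergent marsh,21,bird
spotted seatrout,species,tidal emergent marsh,18,fish
eastern oyster,species,oyster reef,37,invertebrate
American oystercatcher,species,oyster reef,32,bird
red drum,species,oyster reef,21,fish
black skimmer,species,barrier islands,31,bird
Kemp's ridley sea turtle,species,barrier islands,14,reptile
Wilson's plover,species,barrier islands,23,bird
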