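species,score,class
Herring gull,1470,Very high
Great black-backed gull,1143,Very high
Lesser black-backed gull,960,Very high
Iceland gull,817,High
Glaucous gull,817,High
Common gull,750,High
Mediterranean gull,542,High
Northern gannet,512,High
Black-legged kittiwake,420,High
Black-headed gull,400,Moderate
Sandwich tern,397,Moderate
Little gull,390,Moderate
Little tern,373,Moderate
Arctic skua,327,Moderate
Common tern,327,Moderate
Great skua,320,Moderate
Roseate tern,299,Moderate
Black tern,260,Moderate
Black-throated diver,225,Moderate
Red-throated diver,213,Moderate
Shag,208,Moderate
Great northern diver,200,Moderate
Red-necked phalarope,200,Moderate
Sabine's gull,200,Moderate
Great cormorant,187,Low
Pomarine skua,187,Low
Long-tailed skua,163,Low
Arctic tern,163,Low
Common goldeneye,147,Low
Goosander,120,Low
Greater scaup,110,Low
Red-breasted merganser,107,Low
Common scoter,96,Low
White-billed diver,93,Low
Velvet scoter,88,Low
European storm-petrel,75,Low
Leach's storm-petrel,75,Low
Common eider,72,Low
Slavonian grebe,69,Low
Grey phalarope,67,Low
Great-crested grebe,42,Very low
Northern fulmar,39,Very low
Common guillemot,33,Very low
Razorbill,14,Very low
Atlantic puffin,12,Very low
Black guillemot,10,Very low
Little auk,8,Very low
Long-tailed duck,0,Very low
Cory's shearwater,0,Very low
Great shearwater,0,Very low
Sooty shearwater,0,Very low
Manx shearwater,0,Very low
Balearic shearwater,0,Very low
Wilson's storm-petrel,0,Very low
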