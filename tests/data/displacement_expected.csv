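species,score,class
Red-throated diver,32,High
Black-throated diver,30,High
Common scoter,24,High
Great northern diver,22,High
Common goldeneye,18,Moderate
Greater scaup,16,Moderate
Velvet scoter,16,Moderate
Slavonian grebe,16,Moderate
Common eider,14,Moderate
Goosander,14,Moderate
White-billed diver,14,Moderate
Little tern,13,Moderate
Common guillemot,13,Moderate
Razorbill,13,Moderate
Great cormorant,12,Moderate
Shag,12,Moderate
Black guillemot,12,Moderate
Red-breasted merganser,10,Moderate
Sandwich tern,10,Moderate
Roseate tern,10,Moderate
Long-tailed duck,8,Low
Great-crested grebe,8,Low
Black tern,8,Low
Common tern,8,Low
Arctic tern,8,Low
Atlantic puffin,8,Low
Black-headed gull,6,Low
Common gull,6,Low
Great black-backed gull,6,Low
Mediterranean gull,5,Very low
Black-legged kittiwake,5,Very low
Sabine's gull,4,Very low
Little gull,4,Very low
Herring gull,4,Very low
Little auk,4,Very low
Northern gannet,3,Very low
Arctic skua,3,Very low
Great skua,3,Very low
Lesser black-backed gull,3,Very low
Balearic shearwater,2,Very low
Red-necked phalarope,2,Very low
Pomarine skua,2,Very low
Iceland gull,2,Very low
Glaucous gull,2,Very low
Northern fulmar,1,Very low
Cory's shearwater,1,Very low
Great shearwater,1,Very low
Sooty shearwater,1,Very low
Manx shearwater,1,Very low
Wilson's storm-petrel,1,Very low
European storm-petrel,1,Very low
Leach's storm-petrel,1,Very low
Grey phalarope,1,Very low
Long-tailed skua,1,Very low
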