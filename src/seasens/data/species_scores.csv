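species,scientific_name,a_pct_pop,b_survival,c_threat,d_directive,e_blade_pct,f_manoeuvre,g_time_flying,h_nocturnal,i_disturbance,j_habitat
Greater scaup,Aythya marila,1,1,5,3,3,4,2,5,4,4
Common eider,Somateria mollissima,1,4,4,3,2,4,2,3,3,4
Long-tailed duck,Clangula hyemalis,1,1,2,3,0,3,2,3,3,4
Common scoter,Melanitta nigra,2,2,5,3,3,3,2,3,5,4
Velvet scoter,Melanitta fusca,1,3,4,3,3,3,2,3,5,3
Common goldeneye,Bucephala clangula,2,2,4,3,5,3,2,3,4,4
Red-breasted merganser,Mergus serrator,1,3,1,3,5,4,2,2,3,4
Goosander,Mergus merganser,2,3,1,3,5,4,2,2,4,4
Red-throated diver,Gavia stellata,4,3,4,5,5,5,2,1,5,4
Black-throated diver,Gavia arctica,2,4,4,5,5,5,3,1,5,4
Great northern diver,Gavia immer,2,4,4,5,5,5,2,1,5,3
White-billed diver,Gavia adamsii,1,4,1,1,5,5,2,1,5,4
Great-crested grebe,Podiceps cristatus,2,1,1,3,2,4,3,2,3,4
Slavonian grebe,Podiceps auritus,3,1,4,5,2,4,2,2,3,4
Northern fulmar,Fulmarus glacialis,1,5,4,3,1,3,2,4,1,1
Cory's shearwater,Calonectris diomedea,1,5,1,5,0,3,3,3,1,1
Great shearwater,Puffinus gravis,1,5,1,1,0,3,3,3,1,1
Sooty shearwater,Puffinus griseus,1,5,4,3,0,3,3,3,1,1
Manx shearwater,Puffinus puffinus,1,5,4,3,0,3,3,3,1,1
Balearic shearwater,Puffinus mauretanicus,3,4,5,5,0,3,3,3,1,1
Wilson's storm-petrel,Oceanites oceanicus,1,4,1,1,0,1,3,4,1,1
European storm-petrel,Hydrobates pelagicus,1,4,4,5,2,1,3,4,1,1
Leach's storm-petrel,Oceanodroma leucorhoa,1,4,4,5,2,1,3,4,1,1
Northern gannet,Morus bassanus,4,5,4,3,12,3,3,2,2,1
Great cormorant,Phalacrocorax carbo,2,3,2,3,8,4,2,1,4,3
Shag,Phalacrocorax aristotelis,3,3,4,3,8,3,2,1,3,3
Grey phalarope,Phalaropus fulicarius,1,1,1,1,10,1,2,2,1,2
Red-necked phalarope,Phalaropus lobatus,1,1,5,5,10,1,2,2,1,2
Pomarine skua,Stercorarius pomarinus,2,4,1,1,10,1,5,1,1,2
Arctic skua,Stercorarius parasiticus,3,3,5,3,10,1,5,1,1,2
Great skua,Stercorarius skua,5,4,4,3,10,1,4,1,1,2
Long-tailed skua,Stercorarius longicaudus,1,4,1,1,10,1,5,1,1,2
Sabine's gull,Xema sabini,1,3,1,1,20,1,2,2,2,3
Black-headed gull,Chroicocephalus ridibundus,5,3,4,3,20,1,1,2,2,2
Little gull,Hydrocoloeus minutus,2,3,3,5,15,1,3,2,1,3
Mediterranean gull,Larus melanocephalus,1,3,4,5,25,1,2,2,2,2
Common gull,Larus canus,5,3,4,3,25,1,2,3,2,2
Lesser black-backed gull,Larus fuscus,4,5,4,3,30,1,2,3,2,1
Herring gull,Larus argentatus,5,5,5,3,35,2,2,3,2,1
Iceland gull,Larus glaucoides,1,5,3,1,35,2,2,3,2,1
Glaucous gull,Larus hyperboreus,1,5,3,1,35,2,2,3,2,1
Great black-backed gull,Larus marinus,3,5,3,3,35,2,2,3,2,2
Black-legged kittiwake,Rissa tridactyla,2,3,4,3,15,1,3,3,2,2
Black tern,Chlidonias niger,1,4,3,5,10,1,4,1,2,3
Little tern,Sternula albifrons,3,4,4,5,10,1,5,1,2,4
Sandwich tern,Sterna sandvicensis,4,4,4,5,10,1,5,1,2,3
Common tern,Sterna hirundo,2,4,3,5,10,1,5,1,2,3
Roseate tern,Sterna dougallii,2,4,5,5,8,1,5,1,2,3
Arctic tern,Sterna paradisaea,1,4,4,5,5,1,5,1,2,3
Common guillemot,Uria aalge,2,5,4,3,1,4,1,2,3,3
Razorbill,Alca torda,2,5,4,3,0.5,4,1,1,3,3
Black guillemot,Cepphus grylle,1,4,4,1,0.5,4,1,1,3,4
Little auk,Alle alle,1,4,1,3,0.5,3,1,1,2,2
Atlantic puffin,Fratercula arctica,2,5,4,3,0.5,3,1,1,2,3
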