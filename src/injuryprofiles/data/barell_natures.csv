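col,nature_code,name
1,fracture-open,Fracture (open)
2,fracture-closed,Fracture (closed)
3,dislocation,Dislocation
4,sprain-strain,Sprains and strains
5,internal-organ,Internal organ
6,open-wound,Open wounds
7,amputation,Amputations
8,blood-vessel,Blood vessels
9,contusion-superficial,Contusion/superficial
10,crush,Crushing
11,burn,Burns
12,nerve,Nerves
13,unspecified,Unspecified
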