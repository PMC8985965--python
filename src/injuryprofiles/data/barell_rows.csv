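row,region_code,name,iss_region
1,type-1-tbi,Type 1 TBI,head_neck
2,type-2-tbi,Type 2 TBI,head_neck
3,type-3-tbi,Type 3 TBI,head_neck
4,other-head,Other head,head_neck
5,face,Face,face
6,eye,Eye,face
7,neck,Neck,head_neck
8,head-face-neck-unspecified,"Head, face, and neck unspecified",head_neck
9,cervical-sci,Cervical SCI,head_neck
10,thoracic-dorsal-sci,Thoracic/dorsal SCI,chest
11,lumbar-sci,Lumbar SCI,abdomen
12,sacrum-coccyx-sci,Sacrum coccyx SCI,abdomen
13,spine-back-unspecified-sci,Spine and back unspecified SCI,abdomen
14,cervical-vci,Cervical VCI,head_neck
15,thoracic-dorsal-vci,Thoracic/dorsal VCI,chest
16,lumbar-vci,Lumbar VCI,abdomen
17,sacrum-coccyx-vci,Sacrum coccyx VCI,abdomen
18,spine-back-unspecified-vci,Spine and back unspecified VCI,abdomen
19,chest,Chest,chest
20,abdomen,Abdomen,abdomen
21,pelvis-urogenital,Pelvis and urogenital,extremities
22,trunk,Trunk,chest
23,back-buttock,Back and buttock,abdomen
24,shoulder-upper-arm,Shoulder and upper arm,extremities
25,forearm-elbow,Forearm and elbow,extremities
26,wrist-hand-fingers,"Wrist, hand, and fingers",extremities
27,other-upper-extremity,Other and unspecified upper extremity,extremities
28,hip,Hip,extremities
29,upper-leg-thigh,Upper leg and thigh,extremities
30,knee,Knee,extremities
31,lower-leg-ankle,Lower leg and ankle,extremities
32,foot-toes,Foot and toes,extremities
33,other-lower-extremity,Other and unspecified lower extremity,extremities
34,other-multiple,Other/multiple,external
35,unspecified-site,Unspecified,external
36,system-wide,System-wide and late effects,external
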