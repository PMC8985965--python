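start,end,region_code,nature_code
800,801,type-3-tbi,fracture
802,802,face,fracture
805,805,cervical-vci,fracture
807,807,chest,fracture
808,808,pelvis-urogenital,fracture
810,812,shoulder-upper-arm,fracture
813,813,forearm-elbow,fracture
814,817,wrist-hand-fingers,fracture
820,821,upper-leg-thigh,fracture
822,822,knee,fracture
823,824,lower-leg-ankle,fracture
825,826,foot-toes,fracture
850,850,type-2-tbi,internal-organ
851,854,type-1-tbi,internal-organ
860,862,chest,internal-organ
863,868,abdomen,internal-organ
870,871,eye,open-wound
872,873,head-face-neck-unspecified,open-wound
874,874,neck,open-wound
875,875,chest,open-wound
876,877,back-buttock,open-wound
878,878,pelvis-urogenital,open-wound
880,880,shoulder-upper-arm,open-wound
881,881,forearm-elbow,open-wound
882,883,wrist-hand-fingers,open-wound
884,884,other-upper-extremity,open-wound
885,887,wrist-hand-fingers,amputation
890,891,lower-leg-ankle,open-wound
892,893,foot-toes,open-wound
894,894,other-lower-extremity,open-wound
895,897,other-lower-extremity,amputation
900,904,system-wide,blood-vessel
910,919,head-face-neck-unspecified,contusion-superficial
920,924,other-multiple,contusion-superficial
925,929,trunk,crush
940,941,head-face-neck-unspecified,burn
942,942,trunk,burn
943,944,wrist-hand-fingers,burn
945,945,lower-leg-ankle,burn
946,946,other-multiple,burn
948,949,unspecified-site,burn
950,951,eye,nerve
952,952,spine-back-unspecified-sci,internal-organ
953,957,system-wide,nerve
959,959,unspecified-site,unspecified
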