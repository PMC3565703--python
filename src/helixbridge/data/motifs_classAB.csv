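motif_id,family_class,helix_id,generic_start,generic_end,role,expected
KKLH,B,TM1,61,64,g-protein,
DRY,A,TM3,49,51,activation,DRY
YLH,B,TM3,49,51,activation,YLH
DRY_equiv_R,B,TM2,39,39,activation,R
DRY_equiv_H,B,TM2,43,43,activation,H
DRY_equiv_E,B,TM3,46,46,activation,E
W450,A,TM4,50,50,structure,W
W450,B,TM4,50,50,structure,W
IxxL,B,TM5,62,65,g-protein,
KxxK,B,TM6,32,35,g-protein,
polar_lock_T,B,TM6,37,37,activation,T
CWLP,A,TM6,47,50,activation,CWLP
P_kink,B,TM6,42,42,structure,P
NPXXY,A,TM7,49,53,activation,NPIIY
VAVLY,B,TM7,49,53,activation,VAVLY
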