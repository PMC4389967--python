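# Case/control counts per risk-factor level from the published case-control
# analysis (referent = 1 marks each factor's referent level). The joint
# menthol x G6PD factor uses the "grand referent" (unexposed/normal).
# The printed OR 7.120 for the unknown/unknown level is inconsistent with
# its own printed counts (crude OR from 1 case, 25 controls vs the referent
# is 1.480) and is not reproduced; the peak-bilirubin rows of the published
# table are likewise internally inconsistent and are omitted here.
factor,level,cases,controls,referent
sepsis,no,4,67,1
sepsis,yes,12,24,0
gender,female,10,66,1
gender,male,17,103,0
menthol_g6pd,unexposed/normal,1,37,1
menthol_g6pd,unexposed/unknown,10,63,0
menthol_g6pd,unexposed/deficient,3,17,0
menthol_g6pd,unknown/normal,1,10,0
menthol_g6pd,unknown/unknown,1,25,0
menthol_g6pd,unknown/deficient,1,6,0
menthol_g6pd,exposed/normal,0,0,0
menthol_g6pd,exposed/unknown,7,10,0
menthol_g6pd,exposed/deficient,4,2,0
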