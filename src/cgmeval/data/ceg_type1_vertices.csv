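transition,reference_mgdl,cgm_mgdl
AB_upper,0,50
AB_upper,30,50
AB_upper,140,170
AB_upper,280,380
AB_upper,430,550
AB_lower,50,0
AB_lower,50,30
AB_lower,170,145
AB_lower,385,300
AB_lower,550,450
BC_upper,0,60
BC_upper,30,60
BC_upper,50,80
BC_upper,70,110
BC_upper,260,550
BC_lower,120,0
BC_lower,120,30
BC_lower,260,130
BC_lower,550,250
CD_upper,0,100
CD_upper,25,100
CD_upper,50,125
CD_upper,80,215
CD_upper,125,550
CD_lower,250,0
CD_lower,250,40
CD_lower,550,150
DE_upper,0,150
DE_upper,35,155
DE_upper,50,550
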