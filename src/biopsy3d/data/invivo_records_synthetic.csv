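animal_id,bioptome,n_manoeuvres,n_biopsies,major_complication
P1,B1,6,6,False
P2,B1,8,7,False
P3,B1,8,7,False
P4,B2,10,9,False
P5,B2,15,13,False
P6,B2,17,14,False
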