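formulation_id,stage_label,cut_size_um,amount,amount_unit,recovery_volume_ml,n_actuations,flow_rate_lpm
MDI-1,Throat,,172.7,mg_per_L,10,10,30
MDI-1,Stage 1,11.8,5.0,mg_per_L,10,10,30
MDI-1,Stage 2,6.4,3.1,mg_per_L,10,10,30
MDI-1,Stage 3,4.0,6.3,mg_per_L,10,10,30
MDI-1,Stage 4,2.3,16.8,mg_per_L,10,10,30
MDI-1,Stage 5,1.4,11.6,mg_per_L,10,10,30
MDI-1,Stage 6,0.8,4.2,mg_per_L,10,10,30
MDI-1,Stage 7,0.5,1.2,mg_per_L,10,10,30
MDI-1,MOC,0.4,1.2,mg_per_L,10,10,30
MDI-2,Throat,,129.3,mg_per_L,10,10,30
MDI-2,Stage 1,11.8,7.5,mg_per_L,10,10,30
MDI-2,Stage 2,6.4,4.4,mg_per_L,10,10,30
MDI-2,Stage 3,4.0,8.8,mg_per_L,10,10,30
MDI-2,Stage 4,2.3,21.0,mg_per_L,10,10,30
MDI-2,Stage 5,1.4,15.9,mg_per_L,10,10,30
MDI-2,Stage 6,0.8,3.8,mg_per_L,10,10,30
MDI-2,Stage 7,0.5,6.4,mg_per_L,10,10,30
MDI-2,MOC,0.4,6.6,mg_per_L,10,10,30
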