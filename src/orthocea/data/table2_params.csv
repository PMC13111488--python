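arm,cost_eur,p_success,p_partial,p_failure,q_success_after_success,q_success_after_partial,is_baseline
fixed_appliance,2501,1,0,0,1,0,1
removable_plate,1144,0.649,0.274,0.077,0.75,0.5,0
quad_helix,1254,0.821,0.087,0.092,0.75,0.5,0
extra_oral_traction,994,0.574,0.089,0.337,0.75,0.5,0
activator,1152,0.562,0.139,0.299,0.75,0.5,0
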