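arm,expected_cost_eur,expected_effect
fixed_appliance,2501,1
removable_plate,1497,0.66
quad_helix,1545,0.82
extra_oral_traction,1686,0.57
activator,1728,0.56
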