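arm,n,success,partial,failure
fixed_appliance,4000,4000,0,0
removable_plate,1764,1145,484,135
quad_helix,655,538,57,60
extra_oral_traction,101,58,9,34
activator,1327,746,184,397
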