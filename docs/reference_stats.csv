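stat,value
improvement_rate_actor,0.25
improvement_rate_sensor,0.20
mutual_information,0.5
trajectory_length,200
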