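origin,destination,depart_time,model_min,ambulance_min
SMH,RCH,,13,10
SMH,RCH,,13,12
SMH,RCH,,13,11
SMH,RCH,,13,12
SMH,RCH,,13,8
SMH,RCH,,13,27
SMH,RCH,,13,10
SMH,RCH,,13,13
SMH,RCH,,13,9
SMH,RCH,,13,10
SMH,RCH,,13,11
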