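gender,age_group,age_midpoint_y,height_cm,weight_kg
male,30-40,35,182.5,83.2
male,65-75,70,177.3,84.5
female,30-40,35,168.9,69.9
female,65-75,70,164.9,71.4
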