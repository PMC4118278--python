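# UK time-trade-off (TTO) value set for the EQ-5D-3L descriptive system.
# All entries are decrements subtracted from full health (utility 1).
# "constant" applies once if any dimension is above level 1; "n3" applies
# once if any dimension is at level 3.
constant: 0.081
n3: 0.269
mobility_2: 0.069
mobility_3: 0.314
self_care_2: 0.104
self_care_3: 0.214
usual_activities_2: 0.036
usual_activities_3: 0.094
pain_discomfort_2: 0.123
pain_discomfort_3: 0.386
anxiety_depression_2: 0.071
anxiety_depression_3: 0.236
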