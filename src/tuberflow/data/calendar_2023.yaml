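kind: crop_calendar
name: calendar_2023
emergence: 21
tuber_initiation: 43
early_bulk: 56
mid_bulk: 71
late_bulk: 85
senescence_onset: 99
vine_kill: 112
harvest: 135
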