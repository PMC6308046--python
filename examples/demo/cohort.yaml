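# 200-subject table-mode demo cohort (scaled-down arms, default size mixes)
n_cases_train: 35
n_controls_train: 70
n_cases_test: 30
n_controls_test: 65
n_features: 30
n_informative_baseline: 2
n_informative_delta: 2
effect_size: 0.5
delta_effect_size: 1.2
retest_ccc_target: 0.97
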