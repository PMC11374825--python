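# One simulated end-to-end run: both outcomes, fixed (4,3) dfs, median
# padding, subject-average prediction centiles.
simulate: true
n_pregnancies: 20000
surface: inverted_U
outcomes: [gestational_hypertension, preeclampsia]
df_x: 4
df_lag: 3
select_df: false
centile_source: subject_average
padding: median
period_df: 4
subgroup_centile: P95
subgroup_min_size: 200
min_cases: 10
adjusted: true
seed: 7
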