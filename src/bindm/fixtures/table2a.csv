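# Mental-status sub-score cross-tabulation, residents (rows) x consultants
# (columns), 333 paired exams from the published BIND-M inter-rater study.
# Printed weighted kappa: 0.7692 (95% CI: 0.6977, 0.8407).
0,1,2,3
246,11,3,1
12,10,2,0
3,1,27,1
0,2,5,9
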