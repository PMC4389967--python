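# Upward-gaze sub-score cross-tabulation, residents (rows) x consultants
# (columns), 333 paired exams. The gaze sign takes only the values 0 and 3,
# so only the simple kappa applies: printed 0.5802 (95% CI: 0.4055, 0.7549).
0,3
301,12
6,14
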