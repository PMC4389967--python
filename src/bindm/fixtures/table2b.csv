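# Muscle-tone sub-score cross-tabulation, residents (rows) x consultants
# (columns), 333 paired exams. Printed weighted kappa: 0.8430
# (95% CI: 0.7809, 0.9051).
0,1,2,3
259,7,3,1
2,7,0,0
3,3,22,4
1,0,3,18
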