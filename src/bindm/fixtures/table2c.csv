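# Cry sub-score cross-tabulation, residents (rows) x consultants (columns),
# 333 paired exams. Printed weighted kappa: 0.8139 (95% CI: 0.7321, 0.8957)
# (also printed once as 0.81399; same value).
0,1,2,3
279,3,1,3
4,2,1,3
1,0,6,0
2,1,3,24
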