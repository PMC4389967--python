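# Confusion counts of the consultant total BIND-M score against the
# consultant clinical ABE diagnosis at each cutoff (test-positive iff
# score >= cutoff); N = 333, 53 ABE-positive. Known typographical
# discrepancies in the printed metric columns (sensitivity 90.7 at >=3
# where 48/53 = 90.6; 49.6 at >=9 where 26/53 = 49.1; abstract
# specificity 97.7 where 274/280 = 97.9; PPV/NPV swapped at >=7, where
# 37/39 = 94.9 and 278/294 = 94.6; PPV 96.7 at >=8 where 32/33 = 97.0):
# this package reports the arithmetically correct values computed from
# these counts.
cutoff,tp,fn,fp,tn
0,53,0,280,0
1,52,1,33,247
2,50,3,12,268
3,48,5,6,274
4,45,8,5,275
5,44,9,4,276
6,40,13,2,278
7,37,16,2,278
8,32,21,1,279
9,26,27,0,280
10,17,36,0,280
11,11,42,0,280
12,2,51,0,280
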