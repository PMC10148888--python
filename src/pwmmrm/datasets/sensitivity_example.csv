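analysis,subset,comparison,te,p,effect_size
weighted,all,12.5mg_vs_placebo,-4.147,<0.0001,0.289
weighted,all,25mg_vs_placebo,-5.767,<0.0001,0.391
weighted,low_removed,12.5mg_vs_placebo,-2.154,0.043,0.119
weighted,low_removed,25mg_vs_placebo,-5.951,<0.0001,0.329
weighted,high_removed,12.5mg_vs_placebo,-4.533,<0.0001,0.231
weighted,high_removed,25mg_vs_placebo,-6.067,<0.0001,0.299
unweighted,all,12.5mg_vs_placebo,-1.216,0.1558,0.083
unweighted,all,25mg_vs_placebo,-2.905,0.0011,0.197
unweighted,low_removed,12.5mg_vs_placebo,0.092,0.9258,0.005
unweighted,low_removed,25mg_vs_placebo,-2.103,0.0371,0.125
unweighted,high_removed,12.5mg_vs_placebo,-3.791,0.0018,0.185
unweighted,high_removed,25mg_vs_placebo,-5.960,<0.0001,0.281
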