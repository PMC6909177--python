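plan_type,pd_gy,m,b,r2
CAT,15,0.847,0.376,0.947
CAT,18,0.816,0.483,0.935
CAT,21,0.801,0.576,0.926
CAT,24,0.795,0.654,0.921
DCAT,15,0.808,0.373,0.974
DCAT,18,0.765,0.499,0.969
DCAT,21,0.743,0.601,0.965
DCAT,24,0.727,0.680,0.962
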