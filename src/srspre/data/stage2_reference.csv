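plan_type,a,c,r2_slope,n,d,r2_intercept
CAT,1.222,-0.137,0.946,0.237,-1.195,0.9995
DCAT,1.481,-0.226,0.978,0.271,-1.708,0.9999
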