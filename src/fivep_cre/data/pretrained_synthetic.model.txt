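# fivep-cre logistic TSS classifier
format_version=1
predictors=flanking_count,unencoded_g_pct,corrected_expression
transform.flanking_count=log2p1
transform.unencoded_g_pct=identity
transform.corrected_expression=log2p1
intercept=-44.7273839985422
coef.flanking_count=-6.870261039129582
coef.unencoded_g_pct=27.39613807819543
coef.corrected_expression=13.56559032087237
se.intercept=2906.559336144445
se.flanking_count=2101.2891899872798
se.unencoded_g_pct=1445.0623609903053
se.corrected_expression=1851.289470666487
meta.n_pos=113
meta.n_neg=86
meta.method=l2
meta.training_data=synthetic bundle (simulate.SimulationConfig defaults, seed 0)
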