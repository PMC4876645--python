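area,signal,method,onset_ms,k,persistence_ms,alpha,reference_level
M1,perturbation,threshold_3sd,28.0,3.0,20.0,,8.47856858243593
M1,perturbation,running_ttest,74.0,3.0,20.0,0.05,0.0
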