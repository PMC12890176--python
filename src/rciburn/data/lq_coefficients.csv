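cell_type,alpha,beta
monocyte,0.1826,0.0
lymphocyte,0.3481,0.0723
fibroblast,0.5084,0.0549
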