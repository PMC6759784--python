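grandparent,sex,estimate,ci_lower,ci_upper,p_printed
paternal_grandfather,male,0.87,0.46,1.64,0.67
paternal_grandfather,female,0.91,0.43,1.96,0.81
paternal_grandmother,male,0.64,0.32,1.29,0.21
paternal_grandmother,female,2.69,1.05,6.92,0.04
maternal_grandfather,male,1.26,0.68,2.34,0.46
maternal_grandfather,female,1.32,0.58,3.04,0.51
maternal_grandmother,male,0.69,0.35,1.36,0.28
maternal_grandmother,female,0.56,0.22,1.49,0.22
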