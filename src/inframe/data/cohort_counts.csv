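group,probands_tested,probands_with_indel,indels_detected,indels_clinically_reported,indels_modelable,tool_agreement_count
CC,181,12,11,5,5,8
RD,486,99,44,13,3,26
combined,667,112,55,18,8,34
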