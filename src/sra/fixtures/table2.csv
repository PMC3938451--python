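group,stratum,positive,total
af_combined,sra_first_hour_positive,50,85
healthy,sra_first_hour_positive,1,100
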