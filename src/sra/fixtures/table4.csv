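group,stratum,positive,total
af_combined,sra_any_snip_positive,1164,1930
healthy,sra_any_snip_positive,134,2236
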