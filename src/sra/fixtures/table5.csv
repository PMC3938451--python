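group,stratum,positive,total
af_episode_snips,sra_positive,500,504
healthy_snips,sra_positive,24,2821
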