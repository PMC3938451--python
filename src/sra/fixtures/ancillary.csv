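group,stratum,positive,total
af_combined,sra_first_hour,50,85
paroxysmal_af,sra_first_hour,37,70
paroxysmal_af,sra_first_hour_sinus_rhythm,23,54
paroxysmal_af,sra_first_hour_no_holter_af,19,47
paroxysmal_af,post_episode_hour_1,7,9
paroxysmal_af,post_episode_hour_2,5,7
paroxysmal_af,post_episode_hour_3,3,7
paroxysmal_af,holter_af_full,19,70
paroxysmal_af,holter_af_first_hour,13,70
chronic_af,holter_af_full,16,19
chronic_af,holter_af_first_hour,14,19
healthy,holter_af_full,0,100
healthy,sra_first_hour_negative,99,100
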