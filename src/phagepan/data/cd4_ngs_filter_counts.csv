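sample,total_reads,cleaned_reads,removed_reads,total_unique,cleaned_unique,removed_unique
naive,16136813,14126481,2010332,9343121,8706438,636683
round3_eluate,26352345,25317417,1034928,42877,19333,23544
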