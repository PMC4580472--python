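category	lag_total	lag_unique	log_total	log_unique
Raw reads	38092056	9311258	32969156	7713621
3ADT&length filter	19081207	5670799	17749062	4952497
Junk reads	205372	61494	213241	52070
Rfam	2203115	284387	1623385	246854
Repeats	106331	93061	84599	74144
Clean reads	16527710	3230369	13324372	2411293
rRNA	1617108	135768	1197675	123465
tRNA	70911	23706	58754	24125
snoRNA	42572	30220	31274	23939
snRNA	59056	23287	46852	18316
other Rfam RNA	413468	71406	288830	57009
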