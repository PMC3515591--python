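#library	raw_reads	high_quality_reads	clean_reads	unique_srnas	mapped_total	mapped_unique
LC	15521503	15499314	15470689	4210911	10264244	2063684
LS	12492645	12473137	12428654	3172346	8673228	1599019
RC	12726680	12703130	12539747	2696057	9324699	1400836
RS	13233471	13203304	13036443	4125069	8157867	1747201
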