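# Miniature genus -> function rule set in the simplified one-rule-per-line
# dialect: pattern<TAB>function1,function2  (pattern matched as a substring
# of any rank token of the lineage).  Function assignments follow published
# culture-based evidence for the listed genera at coarse grain; this is a
# small curated subset, not a full prokaryotic-function database.
Streptomyces	chemoheterotrophy,aerobic_chemoheterotrophy
Nocardioides	chemoheterotrophy,aerobic_chemoheterotrophy,aromatic_compound_degradation
Devosia	chemoheterotrophy,aerobic_chemoheterotrophy,aromatic_compound_degradation
Amycolatopsis	chemoheterotrophy,aerobic_chemoheterotrophy,aromatic_compound_degradation
Rhodanobacter	chemoheterotrophy,aerobic_chemoheterotrophy
Lysobacter	chemoheterotrophy,aerobic_chemoheterotrophy
Massilia	chemoheterotrophy,aerobic_chemoheterotrophy
Pseudomonas	chemoheterotrophy,aerobic_chemoheterotrophy,aromatic_compound_degradation
Mycobacterium	chemoheterotrophy,aerobic_chemoheterotrophy,aromatic_compound_degradation
Burkholderia	chemoheterotrophy,aerobic_chemoheterotrophy,aromatic_compound_degradation
Sphingomonas	chemoheterotrophy,aerobic_chemoheterotrophy,aromatic_compound_degradation
Phenylobacterium	chemoheterotrophy,aerobic_chemoheterotrophy,aromatic_compound_degradation
Arthrobacter	chemoheterotrophy,aerobic_chemoheterotrophy
Bacillus	chemoheterotrophy
Paenibacillus	chemoheterotrophy
Clostridium	chemoheterotrophy
Rhizobium	chemoheterotrophy,aerobic_chemoheterotrophy
Bradyrhizobium	chemoheterotrophy,aerobic_chemoheterotrophy
Flavobacterium	chemoheterotrophy,aerobic_chemoheterotrophy
Chitinophaga	chemoheterotrophy,aerobic_chemoheterotrophy
Nitrosospira	nitrification
Nitrospira	nitrification
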