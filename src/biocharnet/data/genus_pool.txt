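# Soil bacterial genus pool for synthetic taxonomy assignment.
# Columns: phylum<TAB>class<TAB>order<TAB>family<TAB>genus
Actinobacteriota	Actinobacteria	Streptomycetales	Streptomycetaceae	Streptomyces
Actinobacteriota	Actinobacteria	Propionibacteriales	Nocardioidaceae	Nocardioides
Actinobacteriota	Actinobacteria	Pseudonocardiales	Pseudonocardiaceae	Amycolatopsis
Actinobacteriota	Actinobacteria	Micrococcales	Micrococcaceae	Arthrobacter
Actinobacteriota	Actinobacteria	Micromonosporales	Micromonosporaceae	Micromonospora
Actinobacteriota	Actinobacteria	Corynebacteriales	Mycobacteriaceae	Mycobacterium
Actinobacteriota	Actinobacteria	Frankiales	Geodermatophilaceae	Blastococcus
Actinobacteriota	Thermoleophilia	Gaiellales	Gaiellaceae	Gaiella
Actinobacteriota	Thermoleophilia	Solirubrobacterales	Solirubrobacteraceae	Solirubrobacter
Proteobacteria	Alphaproteobacteria	Hyphomicrobiales	Devosiaceae	Devosia
Proteobacteria	Alphaproteobacteria	Hyphomicrobiales	Rhizobiaceae	Rhizobium
Proteobacteria	Alphaproteobacteria	Hyphomicrobiales	Bradyrhizobiaceae	Bradyrhizobium
Proteobacteria	Alphaproteobacteria	Sphingomonadales	Sphingomonadaceae	Sphingomonas
Proteobacteria	Alphaproteobacteria	Caulobacterales	Caulobacteraceae	Phenylobacterium
Proteobacteria	Alphaproteobacteria	Rhodospirillales	Azospirillaceae	Azospirillum
Proteobacteria	Gammaproteobacteria	Xanthomonadales	Rhodanobacteraceae	Rhodanobacter
Proteobacteria	Gammaproteobacteria	Xanthomonadales	Xanthomonadaceae	Lysobacter
Proteobacteria	Gammaproteobacteria	Burkholderiales	Oxalobacteraceae	Massilia
Proteobacteria	Gammaproteobacteria	Burkholderiales	Comamonadaceae	Ramlibacter
Proteobacteria	Gammaproteobacteria	Burkholderiales	Burkholderiaceae	Burkholderia
Proteobacteria	Gammaproteobacteria	Pseudomonadales	Pseudomonadaceae	Pseudomonas
Proteobacteria	Gammaproteobacteria	Steroidobacterales	Steroidobacteraceae	Steroidobacter
Proteobacteria	Gammaproteobacteria	Nitrosococcales	Nitrosomonadaceae	Nitrosospira
Acidobacteriota	Acidobacteriae	Acidobacteriales	Acidobacteriaceae	Edaphobacter
Acidobacteriota	Blastocatellia	Blastocatellales	Blastocatellaceae	Blastocatella
Acidobacteriota	Vicinamibacteria	Vicinamibacterales	Vicinamibacteraceae	Vicinamibacter
Acidobacteriota	Holophagae	Holophagales	Holophagaceae	Holophaga
Chloroflexi	Chloroflexia	Chloroflexales	Roseiflexaceae	Roseiflexus
Chloroflexi	Anaerolineae	Anaerolineales	Anaerolineaceae	Anaerolinea
Chloroflexi	Ktedonobacteria	Ktedonobacterales	Ktedonobacteraceae	Ktedonobacter
Firmicutes	Bacilli	Bacillales	Bacillaceae	Bacillus
Firmicutes	Bacilli	Paenibacillales	Paenibacillaceae	Paenibacillus
Firmicutes	Clostridia	Clostridiales	Clostridiaceae	Clostridium
Bacteroidota	Bacteroidia	Chitinophagales	Chitinophagaceae	Chitinophaga
Bacteroidota	Bacteroidia	Chitinophagales	Chitinophagaceae	Flavisolibacter
Bacteroidota	Bacteroidia	Cytophagales	Microscillaceae	Ohtaekwangia
Bacteroidota	Bacteroidia	Flavobacteriales	Flavobacteriaceae	Flavobacterium
Gemmatimonadota	Gemmatimonadetes	Gemmatimonadales	Gemmatimonadaceae	Gemmatimonas
Verrucomicrobiota	Verrucomicrobiae	Chthoniobacterales	Chthoniobacteraceae	Chthoniobacter
Verrucomicrobiota	Verrucomicrobiae	Opitutales	Opitutaceae	Opitutus
Planctomycetota	Planctomycetes	Pirellulales	Pirellulaceae	Pirellula
Planctomycetota	Phycisphaerae	Tepidisphaerales	Tepidisphaeraceae	Tepidisphaera
Myxococcota	Myxococcia	Myxococcales	Myxococcaceae	Corallococcus
Myxococcota	Polyangia	Haliangiales	Haliangiaceae	Haliangium
Nitrospirota	Nitrospiria	Nitrospirales	Nitrospiraceae	Nitrospira
Patescibacteria	Saccharimonadia	Saccharimonadales	Saccharimonadaceae	Saccharimonas
Patescibacteria	Parcubacteria	Candidatus_Adlerbacteria	Candidatus_Adlerbacteria_fam	Adlerbacteria
Deinococcota	Deinococci	Deinococcales	Deinococcaceae	Deinococcus
Armatimonadota	Armatimonadia	Armatimonadales	Armatimonadaceae	Armatimonas
Bdellovibrionota	Bdellovibrionia	Bdellovibrionales	Bdellovibrionaceae	Bdellovibrio
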