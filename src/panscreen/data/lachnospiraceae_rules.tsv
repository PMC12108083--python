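taxon	class
Paenibacillaceae	contaminant
Pasteurellales	contaminant
Negativicutes	contaminant
Desulfovibrionales	contaminant
Erysipelotrichia	contaminant
Oscillospiraceae	contaminant
Clostridia	consistent
Clostridiales	consistent
unclassified Clostridiales	consistent
Clostridiaceae	consistent
Ruminococcaceae	consistent
Eubacteriaceae	consistent
Lachnospiraceae	consistent
unclassified Lachnospiraceae	consistent
Blautia	consistent
Oribacterium	consistent
Butyrivibrio	consistent
Bacteria	ambiguous
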