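# Controlled vocabulary of tailoring reaction terms (one per line, editable).
Acetylation
Acylation
Amination
Biaryl bond formation
Carboxylation
Cyclization
Deamination
Decarboxylation
Dehydration
Dehydrogenation
Epimerization
Glycosylation
Halogenation
Heterocyclization
Hydrolysis
Hydroxylation
Macrolactamization
Macrolactonization
Methylation
Oxidation
Phosphorylation
Prenylation
Reduction
Sulfonation
Other
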