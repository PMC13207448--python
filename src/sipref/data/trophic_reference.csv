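lineage,trophic_class,evidence
Scytonema hyalinum,fixer,photoautotrophic terrestrial cyanobacterium
Oscillatoriales,fixer,photoautotrophic cyanobacterial order
Cyanobacteria,fixer,oxygenic photoautotrophs
Blastococcus mobilis,fixer,genomic chemolithoautotrophic potential with mixotrophy
Modestobacter altitudinis,fixer,genomic chemolithoautotrophic potential with mixotrophy
Geodermatophilus,fixer,chemoautotrophic potential inferred from close relatives
Pseudonocardia,fixer,autotrophic CO/H2-oxidising members reported
Noviherbaspirillum,fixer,autotrophic carbon-fixation genes in congeners
Mesorhizobium,fixer,chemolithoautotrophic members reported
Solirubrobacter,fixer,autotrophic potential inferred from phylogenetic neighbours
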