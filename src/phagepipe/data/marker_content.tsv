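# Lifestyle-marker family content per genome.  A "-" family marks a genome
# with no lifestyle markers detected.
genome_id	family_id	role
SeAO1	-	-
SeEM1	-	-
SeEM2	-	-
SeEM4	-	-
SeF3a	-	-
SeF6a	-	-
SeF1	phrog_66	rdf
SeF1	phrog_130	antirepressor
SeF2	-	-
SeF6b	-	-
Salfasec13b	phrog_216	integrase
Salfasec13b	phrog_550	ciii
Salfasec13b	phrog_6201	ci_repressor
Salfasec13b	phrog_725	cii
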