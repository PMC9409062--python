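# Worked curation scenarios: a trio with one strongly and two weakly
# affiliated overlappers (discard the weak pair), a trio of mutually
# overlapping strong affiliations (keep all three), and a singleton ORF
# completely containing a reliably predicted tRNA on the same strand
# (discard the ORF).  Affiliation metrics for the weak-pair trio are
# transcribed from the published worked example; coordinates are synthetic
# geometry realizing the described overlaps.
case	feature_type	feature_id	start	end	strand	family_id	probability	evalue	isotype
weak_pair_trio	orf	gp_014	1200	1799	+	phrog_32723	55	1.1	-
weak_pair_trio	orf	gp_015	1000	2997	+	phrog_519	99.5	1.4E-18	-
weak_pair_trio	orf	gp_016	1500	2297	+	phrog_8445	23.5	7.4	-
all_strong_trio	orf	gp_212	10000	11199	+	phrog_101	99.0	1.0E-20	-
all_strong_trio	orf	gp_213	10450	11649	+	phrog_102	95.0	1.0E-15	-
all_strong_trio	orf	gp_214	10300	10899	+	phrog_103	98.5	1.0E-10	-
trna_overlap	orf	gp_222	5000	5398	+	-	-	-	-
trna_overlap	trna	tRNA6-Val	5100	5175	+	-	-	-	Val
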