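# ClinVar variants in the POLG dual-coding region that are synonymous or
# UTR with respect to the main ORF, with their published predicted effects
# on the ORF-Y and ORF-Z translation products (GRCh38.p12 positions).
# Fixture notes: the published row for rs892999189 prints the synonymous
# alt as "L23L" in the substitution column; this package renders
# synonymous alts as "no change" and stores the published string verbatim.
# The published rows for rs375445567 and some other multi-allelic variants
# print a single consequence for multiple alts; stored verbatim.
rsid	change	position	orf_y	orf_z
768005050	G>A	chr15:89333152	no change	not in ORF
1057522857	C>T	chr15:89330213	G259S	not in ORF
750915606	G>A	chr15:89333227	P194S	not in ORF
766842881	G>C	chr15:89333233	L192V	not in ORF
1028326668	C>T	chr15:89333239	G190R	not in ORF
886044612	C>T	chr15:89333254	G185S	not in ORF
1057520491	G>A	chr15:89333266	P181S	not in ORF
375445567	G>A/C	chr15:89333271	A179G	not in ORF
1567194008	A>G	chr15:89333283	V175A	not in ORF
1567194019	C>T	chr15:89333287	A174T	not in ORF
779981823	C>T	chr15:89333302	G169R	not in ORF
761417163	G>A	chr15:89333332	P159S	not in ORF
558958919	C>A/G/T	chr15:89333371	A146T/A146S/A146P	not in ORF
1057524724	C>A	chr15:89333374	A145S	not in ORF
1057521700	G>C	chr15:89333419	L130V	not in ORF
56221189	C>A	chr15:89333422	A129S	not in ORF
376266682	G>A	chr15:89333425	R128W	not in ORF
144439703	G>A/C	chr15:89333491	R106G/R106W	not in ORF
774537232	G>A/C/T	chr15:89333518	L97I/L97V/L97F	not in ORF
1241802528	A>G	chr15:89333535	I91T	not in ORF
751225754	C>A/G/T	chr15:89333545	A88T/A88P/A88S	not in ORF
745310138	T>C	chr15:89333569	I80V	not in ORF
1555454318	T>C	chr15:89333575	S78G	not in ORF
372383277	C>A	chr15:89333578	A77S	not in ORF
796052878	C>T	chr15:89333593	A72T	not in ORF
587781118	T>A/C	chr15:89333596	T71A/T71S	not in ORF
587781117	C>G/T	chr15:89333599	A70T/A70P	not in ORF
1453538834	C>T	chr15:89333602	A69T	not in ORF
766501874	C>T	chr15:89333605	A68T	not in ORF
570989155	C>T	chr15:89333626	A61T	not in ORF
794727268	C>A	chr15:89333641	A56S	not in ORF
587781116	G>A	chr15:89333668	R47C	not in ORF
944054671	T>C/G	chr15:89333695	S38R/S38G	not in ORF
1378670216	C>G	chr15:89333701	G36R	not in ORF
535213599	G>A/C	chr15:89333716	R31G/R31C	not in ORF
1482684558	G>A	chr15:89333722	R29C	not in ORF
1060504037	G>A	chr15:89333725	R28W	not in ORF
1057523280	C>T	chr15:89333734	E25K	not in ORF
892999189	G>A/C	chr15:89333740	L23V/L23L	not in ORF
750010376	C>A	chr15:89333775	R11L	not in ORF
1284152513	A>C	chr15:89333782	S9A	not in ORF
1057521902	G>A	chr15:89333802	P2L	not in ORF
553331485	T>C	chr15:89333821	not in ORF	no change
3087378	G>A	chr15:89333834	not in ORF	S20F
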