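id	notation	deleted_proximal	deleted_distal	pcr_verified	large_insert_only	uncertainty_bp	note
1	←9700293 **T** 37017235←	.	.	0	0	500	.
2	←10208816 24726221→	.	.	0	0	500	.
3	←10708238 27263491→	.	.	0	0	500	.
4	←10603042 _N800_ 47916774→	.	.	1	1	0	800 bp alpha-satellite insertion
5	←10739714 **TG** 26376257←	.	.	1	0	0	.
6	→11085336 18942901←	.	18943090-19761690	0	0	500	.
7	←11086535 24460837→	.	.	0	1	3000	.
8	→11167165 25728012←	.	25728011-25728022	1	0	0	.
9	→15970237 16083578→	15970237-15970259	.	1	0	0	.
10	←17769030 26038660→	.	26038424-26038659	1	0	0	.
11	→17764356 **GG** 17771310←	.	.	1	0	0	.
12	←17770361 **C** 19761690→	.	18943090-19761690	1	1	0	.
13	→18734159 **ACTCCTGAAATCCCAACACTTTGGGAGGC** 24880958→	18734399-18873580	24880850-24880910	1	1	0	distal breakpoint between 24880910 and 24880958
14	→20514026 **CTT** 24460819←	.	.	1	0	0	.
15	←20514023 20756929→	.	20756923-20756928	1	0	0	.
16	→20756922 **AG** 23648470→	20756923-20756928	.	1	0	0	bases 23648470-23648476 appear in two junction fragments
17	→20893994 **C** 23648476←	.	.	1	0	0	bases 23648470-23648476 appear in two junction fragments
18	AT←20893996 _TATATTATATATTATATATTATATA_ 24725875←	.	24725876-24726137	1	0	0	.
19	→22612235 _N950_ 23294101←	.	.	1	1	0	950 bp insertion homologous to an unplaced chr4 contig
20	←23198373 _ATATAAATATA_ 23306917→	.	.	1	0	0	bases 23306917-23306930 appear in two junction fragments
21	→23306930 **T** 25728022→	.	25728011-25728022	1	0	0	bases 23306917-23306930 appear in two junction fragments
22	→26038424 **T** 27263316←	26038424-26038659	.	1	0	0	.
23	→33223436 **CC** 36370289→	33223437-33223572	33640333-36370288	1	0	0	.
24	←33223573 _N145_ 45795618→	33223437-33223572	.	1	0	0	41 bp unknown + 49 bp chr21:9826532-9826580 + 55 bp unknown
25	←37017239 45795619←	.	.	1	0	0	.
26	AT→44314438 _TAATATATAATATATATATTAATATATATATATATATTATATAT_ 47322101→	44314439-44314673	.	1	0	0	AT repeat most likely from the 44314438 side
27	→46868313 _CATATC_ 47916772←	46868314-47322100	.	1	0	0	.
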