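variant	motif	coding_prediction	outcomes	rna_effect	protein_effect	prior_class	prior_reason
c.7806-9T>G	Pyr	intronic	ex17 skipping=41.5;ivs16-ins8=36.3;ex17-del69=22.2	r.[7806_7976del,7805_7806ins7806-8_7806-1,7806_7874del]	p. [A2603_R2659del; R2602Sfs*49; A2603_R2625del]
c.7806-2A>G	[-] 3'SS	intronic	ex17-del20=51.8;ex17-del69=28.1;ex17 skipping=20.1	r.[7806_7825del,7806_7874del,7806_7976del]	p.[A2603Cfs*8;A2603_R2625del;A2603_R2659del]
c.7806-1G>A	[-] 3'SS	intronic	ex17-del1=100	r.[7806_7807del]	p.A2603Lfs*45
c.7806-1G>T	[-] 3'SS	intronic	ex17-del20=100	r.7806_7825del	p.A2603Cfs*8
c.7806-1_7806-2dup	[+]3'SS	intronic	ex17-insAG=92.6;ex17 skipping=5.1;ex17-del69=2.3	r.[7805_7806insAG,7806_7976del,7806_7874del]	p. [A2603Gfs*46; A2603_R2659del; A2603_R2625del]
c.7975A>G	[-] 5'SS	missense	FL=73.8;ex17 skipping=26.2	r.[7975a>g,7806_7976del]	p. [R2659G;A2603_R2659del]
c.7976G>C	[-] 5'SS	missense	ex17 skipping=100	r.7806_7976del	p.A2603_R2659del
c.7976G>A	[-] 5'SS	missense	ex17 skipping=100	r.7806_7976del	p.A2603_R2659del
c.7976+1G>A	[-] 5'SS	intronic	ex17 skipping=100	r.7806_7976del	p.A2603_R2659del
c.7977-7C>G	[+]3'SS/Pyr	intronic	ex18-ins6=78.4;ex18 skipping=21.6	r.[7976_7977ins6,7977_8331del]	p.[Y2658_R2659insSF; Y2660Ffs*43]
c.7977-6T>G	Pyr	intronic	FL=66.7;ex18 skipping=31;ex18-del191=2.3	r. [=, 7977_8331del,7977_8167del]	p. [=; Y2660Ffs*43;Y2660Wfs*6]
c.7977-3_7978del	[-] 3'SS	intronic	ex18 skipping=90;ex18-del191=10	r.[7977_8331del,7977_8167del]	p.[Y2660Ffs*43;Y2660Wfs*6]
c.7977-2A>T	[-] 3'SS	intronic	ex18 skipping=93.3;ex18-del191=6.7	r.[7977_8331del,7977_8167del]	p.[Y2660Ffs*43;Y2660Wfs*6]
c.7977-1G>T	[-] 3'SS	intronic	ex18 skipping=91.5;ex18-del191=7;ex18-del236=1.5	r.[7977_8331del,7977_8167del,7977_8212del]	p.[Y2660Ffs*43;Y2660Wfs*6;R2659Sfs*26]
c.7977-1G>C	[-] 3'SS	intronic	ex18 skipping=89.8;ex18-del191=10.2	r.[7977_8331del,7977_8167del,?]	p.[Y2660Ffs*43; Y2660Wfs*6;?]
c.7985C>G	[-]ESE/[+]ESS	missense	ex18 skipping=90.2;ex18-del191=5;others=4.8	r.[7977_8331del,7977_8167del,?]	p.[Y2660Ffs*43; Y2660Wfs*6;?]
c.7988A>T	[+]5'SS [-]ESE	missense	FL=84.2;ex18 skipping=8.6;others=7.2	r.[7988a>u,7977_8331del,?]	p.[E2663V;Y2660Ffs*43;?]
c.7992T>A	[-]ESE/[+]ESS	synonymous	FL=68.6;ex18 skipping=31.4	r.[7992u>a,7977_8331del]	p. [=; Y2660Ffs*43]
c.8007A>G	[-]ESE/[+]ESS	synonymous	FL=84.8;ex18 skipping=15.2	r.[8007a>g,7977_8331del]	p. [=; Y2660Ffs*43]
c.8009C>A	[-]ESE/[+]ESS	nonsense	ex18 skipping=91.2;ex18-del191=4.8;FL=4	r.[7977_8331del,7977_8167del,8009c>a,?]	p. [Y2660Ffs*43; Y2660Wfs*6;S2670*;?]
c.8009C>T	[-]ESE/[+]ESS	missense	FL=76.6;ex18 skipping=23.4	r.[8009c>u,7977_8331del]	p.[S2670L;Y2660Ffs*43]
c.8009C>G	[-]ESE/[+]ESS	missense	FL=79.9;ex18 skipping=20.1	r.[8009c>g,7977_8331del]	p.[S2670W;Y2660Ffs*43]
c.8023A>G	[+]5'SS	missense	ex18-del309=93;others=7	r.[8023_8331del,?]	p.[Ile2675_K2777del;?]
c.8035G>T	[+]5'SS	missense	ex18-del298=93.6;878nt=4;FL=2.4	r.[8034_8331del,?]	p.[D2679Ffs*43;?]
c.8072C>T	[-]ESE/[±]ESS	missense	FL=94.9;ex18 skipping=5.1	r.[8072c>u,7977_8331del]	p.[S2691F;Y2660Ffs*43]
c.8168A>G	[+]5'SS	missense	FL=69.6;ex18-del164=25.9;ex18 skipping=4.5	r.[8168a>g,8168_8331del,7977_8331del]	p.[D2723G;G2724Ffs*3; Y2660Ffs*43]	likely_pathogenic	protein function
c.8249_8250del	[-]ESE/[-]ESS	frameshift	FL=93.0;ex18 skipping=7.0	r.[8249_8250del,7977_8331del]	p.[K2750Asnfs*13; Y2660Ffs*43]	likely_pathogenic	truncation
c.8331G>A	[-] 5'SS	synonymous	ex18 skipping=52;FL=40.7;others=7.3	r.[8331g>a,7977_8331del,?]	p. [=; Y2660Ffs*43;?]
c.8331+1G>T	[-] 5'SS	intronic	ex18 skipping=81;ex18-del157=6.4;ex17-del151+ex18 skipping=6.1;ivs17-ret58+ex18 skipping=3.7;others=2.8	r.[7977_8331del,8175_8331del,7826_8331del, 7977_8331delins7976+1_7976+58]	p. [Y2660Ffs*43;W2725*; G2609Dfs*4; Y2660Qfs*3]
c.8331+2T>C	[-] 5'SS	intronic	ex18 skipping=87.1;ex17-del151+ex18 skipping=12.9	r.[7977_8331del,7826_8331del]	p.[Y2660Ffs*43; G2609Dfs*4]
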