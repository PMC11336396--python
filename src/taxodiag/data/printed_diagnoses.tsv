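species	genus	marker	region_prefix	start	end	barcode	allowance	separator	scope	provenance
Pseudoentrophospora kesseensis	Pseudoentrophospora	ITS	ITS2	127	146	gaaccgcaaattacgcatta	1	,	other species of Pseudoentrophospora and Entrophospora	protologue
Pseudoentrophospora kesseensis	Pseudoentrophospora	LSU		486	515	gaacaggtcaacatcaattcttattgccat	1	,	other species of Pseudoentrophospora and Entrophospora	protologue
Hoforsa rebekkae	Hoforsa	ITS	ITS2	108	127	ggratcycccgaggtgtgaaac	1	;	other species of Hoforsa	protologue
Hoforsa rebekkae	Hoforsa	LSU		546	565	ctcctggtgctctcacccgt	0	;	other species of Hoforsa	protologue
Kahvena rebeccae	Kahvena	ITS	ITS2	200	218	cattcgcaggaatagccag	1	;	other species of Kahvena	protologue
Kahvena rebeccae	Kahvena	LSU		653	683	acgcaagctccagatcgaatctccgggctaa	1	;	other species of Endogonomycetes	protologue
Kelottijaervia shannonae	Kelottijaervia	ITS		212	239	taatgtgagtgcaggaaatattatgact	1	;	other species of Kelottijaervia	protologue
Kelottijaervia shannonae	Kelottijaervia	LSU		600	619	ctttggggtggcggtcgctg	1	;	other species of Kelottijaervia	protologue
Kungsaengena shadiae	Kungsaengena	ITS	ITS2	25	44	tgggaacccatttcgtcgga	1	;	other species of Kungsaengena	protologue
Kungsaengena shadiae	Kungsaengena	LSU		665	694	cgttggggctgggacgcccgtcgctcgcac	1	;	other species of Kungsaengena	protologue
Langduoa dianae	Langduoa	ITS		87	106	actgagccttgcagcaacaatctccccttt	0	;	other species of Langduoa	protologue
Langduoa dianae	Langduoa	LSU		617	636	ccctctcggggggctgggga	0	;	other species of Langduoa	protologue
Lehetua indrekii	Lehetua	ITS		219	248	ttataatcttacgaagtactgaggtgatta	1	;	other species of Lehetua	protologue
Lehetua indrekii	Lehetua	LSU		515	546	aactaaaggratgtggctcctcggagtgttta	1	;	other species of Lehetua	protologue
Lokruma stenii	Lokruma	ITS		159	178	taacttaattttttcccgag	1	;	other species of Lokruma	protologue
Moostea stephanieae	Moostea	ITS		68	97	gcagatgatcgtgagggagttctcttcttc	1	;	other species of Moostea	protologue
Moostea stephanieae	Moostea	LSU		436	455	tgggcttctgctccggcgta	1	;	other species of Moostea	protologue
Nikkaluokta mahdiehiae	Nikkaluokta	ITS		97	116	cctgggcaaatttttttttc	1	;	other species of Nikkaluokta	protologue
Nikkaluokta mahdiehiae	Nikkaluokta	LSU		687	717	cttggatataagaagtggaatctacacaaat	1	;	other species of Nikkaluokta	protologue
Parnigua craigii	Parnigua	ITS		51	80	actgagccttgcagcaacaatctccccttt	0	;	other species of Parnigua	protologue
Parnigua craigii	Parnigua	LSU		444	463	ggcgggaaatcagcccccct	0	;	other species of Parnigua	protologue
Riederberga sylviae	Riederberga	ITS	ITS2	186	215	gctttggacggcatgcgaatctgcatcaca	1	;	other species of Riederberga	protologue
Riederberga sylviae	Riederberga	LSU		656	685	tcaccaatcgacgtcaatcggcatgcgtct	1	;	other species of Riederberga	protologue
Ruua coralieae	Ruua	ITS		217	243	gaaaaaaaaagaaaggaaagaaaaggt	1	;	other species of Ruua	protologue
Ruua coralieae	Ruua	LSU		470	489	tagtgcacttgctttcgcac	0	;	other species of Ruua	protologue
Tammsaarea vivikae	Tammsaarea	ITS		228	257	ggaccgagaaggcgcaatagttgaacaatt	1	;	other species of Tammsaarea and other species of Endogonomycetes	protologue
Tammsaarea vivikae	Tammsaarea	LSU		585	604	ataactatcggacaaagttt	1	;	other species of Tammsaarea and other species of Endogonomycetes	protologue
Unemaeea nathalieae	Unemaeea	ITS	5.8S	122	151	gtcagtgtttgccacggagtatgccggctt	0	;	other species of Unemaeea	protologue
Unemaeea nathalieae	Unemaeea	LSU		694	723	gggcttgtcatggcagagggacacgtcgta	0	;	other species of Endogonomycetes	protologue
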