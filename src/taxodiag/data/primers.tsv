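name	sequence	orientation	target_region	note
LR3-End2	aycattahgycagcgacc	reverse	LSU	reverse primer covering >99% of Endogonomycetes
LR3-End2a	aycattahgycagccgtta	reverse	LSU	reverse primer for Unemaeeaceae
LF350End	ccgatagcgaacaagtac	forward	LSU	forward primer, also amplifies many other fungi
AMV4.5NF		forward	SSU	sequence not printed; supply from the primer literature
AMDGR		reverse	SSU	sequence not printed; supply from the primer literature
AM-Sal-F		forward	SSU	sequence not printed; supply from the primer literature
FRE-F		forward	SSU	sequence not printed; supply from the primer literature
FRE-R		reverse	SSU	sequence not printed; supply from the primer literature
ITS1F		forward	ITS1	sequence not printed; supply from the primer literature
ITS1		forward	ITS1	sequence not printed; supply from the primer literature
gITS7ngs		forward	ITS2	sequence not printed; supply from the primer literature
ITS4ngsUni		reverse	ITS2	sequence not printed; supply from the primer literature
ITS9munngs		forward	ITS2	sequence not printed; supply from the primer literature
ITS1catta		forward	ITS1	sequence not printed; supply from the primer literature
wSSUmcf		forward	SSU	sequence not printed; supply from the primer literature
wLSUmbr		reverse	LSU	sequence not printed; supply from the primer literature
LROR		forward	LSU	sequence not printed; supply from the primer literature
TW13		reverse	LSU	sequence not printed; supply from the primer literature
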