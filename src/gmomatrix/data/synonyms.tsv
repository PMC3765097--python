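# Synonym table: one "synonym<TAB>canonical" pair per line.
# Seeded with the historically ambiguous element names; edit freely.
pE35S	p35S
pFMV34S	pFMV
pCmoVb	pFMV
peFMV	pFMV
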