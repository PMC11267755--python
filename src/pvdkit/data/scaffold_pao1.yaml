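residues:
- Ser
- Arg
- Ser
- fOHOrn
- Lys
- fOHOrn
- Thr
- Thr
chromophore: Chr-sa
side_chain_form: succinamide
cycle_span:
- 5
- 8
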