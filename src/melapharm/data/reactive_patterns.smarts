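# Reactive functional groups removed during screening-library preparation.
# One SMARTS per line: <pattern><whitespace><name>.  Lines starting with '#'
# are comments.  This list is the package's own, declared set (acyl halides,
# aldehydes, Michael acceptors, isocyanates, activated alkyl halides); it is
# intentionally short and auditable rather than exhaustive.
[CX3](=O)[F,Cl,Br,I]	acyl_halide
[CX3H1](=O)[#6]	aldehyde
C=[CH1]C(=O)[#6]	michael_acceptor_vinyl_ketone
[NX2]=C=O	isocyanate
[CH2X4][Br,I]	alkyl_halide
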