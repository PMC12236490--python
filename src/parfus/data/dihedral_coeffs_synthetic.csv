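# SYNTHETIC generic dihedral cosine-series coefficients, kJ/mol and rad.
pair,n,k,delta
default,1,0.3,0.0
default,2,0.15,3.14159265
default,3,0.3,0.0
default,4,0.05,0.0
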