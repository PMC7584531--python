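# mtDNA variants previously reported to associate with LHON
# columns: variant, annotation
m.3497C>T	reported/secondary
m.8836A>G	reported
m.14831G>A	reported
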