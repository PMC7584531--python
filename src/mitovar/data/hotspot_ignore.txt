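# Hypervariable/hotspot positions excluded from haplogroup scoring
# (standard practice; prevents spurious mismatch penalties from
# recurrent mutations and the rCRS 3107 placeholder).
309
315
515
523
3107
16519
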