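seed	mirna_name
ACTTGA	hsa-miR-26a
ACTGGA	hsa-miR-145
TAGGAA	hsa-miR-384
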