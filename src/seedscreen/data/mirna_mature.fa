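>hsa-miR-26a MIMAT0000082
UUCAAGUAAUCCAGGAUAGGCU
>hsa-miR-145 MIMAT0000437
GUCCAGUUUUCCCAGGAAUCCCU
>hsa-miR-384 MIMAT0001075
AUUCCUAGAAAUUGUUCAUA
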