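number	english_per_million	spanish_per_million
1	856	1079
2	707	928.17
3	368	468.93
4	224	248.99
5	204	234.11
6	156	155.44
7	87	85.75
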