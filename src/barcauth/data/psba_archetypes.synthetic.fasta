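>long_archetype species=synthetic region=psbA-trnH source=synthetic_archetype
AATTTTAAAATTTAATTTTTCGACGGATCACGGCGGCCGGCGGAAACCGCCGGCCGCCGTGCATCCAGTCTTTAAAATTTTAAATTAAAA
>short_archetype species=synthetic region=psbA-trnH source=synthetic_archetype
AATTTTAAAATTTAATTTTTCGACGGATCACGGCGGCAAAGCCGCCGTGCATCCAGTCTTTAAAATTTTAAATTAAAA
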