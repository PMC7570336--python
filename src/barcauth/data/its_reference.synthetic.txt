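>HperforatumITS.synthetic segment=ITS1var threshold=0.95 species=Hypericum_perforatum
CCTGAACGTTgGATCCAYTTGCAACGGTcTAGGCTTAAGG
>HperforatumITS.synthetic segment=ITS2var threshold=0.95 species=Hypericum_perforatum
TTGACCGGATCAAGrTCCAGTAaGGTTCACGGTTCGAWCC
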