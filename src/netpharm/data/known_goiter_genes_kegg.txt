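# KEGG_H00251
DUOX2
DUOXA2
FOXI1
IYD
SLC26A4
SLC5A5
TG
TPO
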