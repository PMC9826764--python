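CXCL1
ICAM1
PHLPP2
ZKSCAN1
ATP9A
NCF4
CACNA2D1
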