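symbol	chromosome
EIF1AX	X
DDX3X	X
EIF2S3	X
PABPC5	X
EIF1AY	Y
DDX3Y	Y
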