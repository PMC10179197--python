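canonical	alias
VARS	VARS1
HARS	HARS1
WARS	WARS1
TARSL2	TARS3
KARS	KARS1
NARS	NARS1
QARS	QARS1
EPRS	EPRS1
MARS	MARS1
AARS	AARS1
CARS	CARS1
DARS	DARS1
GARS	GARS1
IARS	IARS1
LARS	LARS1
RARS	RARS1
SARS	SARS1
TARS	TARS1
YARS	YARS1
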