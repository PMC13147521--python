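arm	bp	cM
2L	0	0.0
2L	3000000	6.0
2L	8000000	20.0
2L	13000000	36.0
2L	18000000	48.0
2L	22000000	55.0
2L	23513712	55.0
2R	0	55.0
2R	5900000	55.0
2R	9000000	60.0
2R	13000000	72.0
2R	17000000	85.0
2R	21000000	96.0
2R	25286936	107.0
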