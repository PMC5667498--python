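name	coordinates	printed_length	context
1p36.13	1:20,253,380–20,259,203 (−)	5824	intergenic
1p22.2	1:89,551,973–89,554,309	2337	intergenic
1q22	1:155,661,620–155,669,312 (−)	7693	DAP3 (+)
6p22.1	6:27,155,300–27,164,058 (+)	8759	intergenic
6p21.33a	6:31,952,469–31,958,829 (−)	6361	C4A (+)
6p21.33b	6:31,985,207–31,991,567 (−)	6361	C4B (+)
6q22.31	6:122,825,990–122,833,238 (−)	7249	PKIB (+)
19p13.2	19:7,860,947–7,865,932 (−)	4986	intergenic
19q13.41	19:52,964,148–52,969,750 (−)	5458	ZNF578 (+)
Yq11.221	Y:15,105,784–15,113,006 (−)	7223	L1M3f (−)
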