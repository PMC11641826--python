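gene	chrom	start	end
OPRM1	chr6	154039240	154132356
OPRD1	chr1	28812170	28871267
DRD2	chr11	113409605	113475398
BDNF	chr11	27654893	27700455
APBB2	chr4	40810027	41214542
KCNG2	chr18	79797938	79900100
KCNC1	chr11	17734781	17783057
CNIH3	chr1	224616317	224740554
RGMA	chr15	93035271	93089211
DRD3	chr3	114127580	114179052
DRD4	chr11	637269	640706
NRXN3	chr14	78170373	79868291
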