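drug,cmax_min_uM,cmax_max_uM,risk_class,vehicle
Cisplatin,30,30,High,DMSO (0.5%)
Carboplatin,24,149,Intermediate,DMSO (0.5%)
Canagliflozin,2.75,10.5,High,DMSO (0.5%)
Dapagliflozin,0.176,0.41,Intermediate,DMSO (0.5%)
Gentamicin,41.2,41.2,High,Media
Streptomycin,73.2,73.2,Intermediate,DMSO (0.5%)
Tenofovir,1.1,1.1,High,DMSO (0.5%)
Adefovir,0.07,0.07,High,DMSO (0.5%)
Telithromycin,2.5,2.5,High,DMSO (0.5%)
Rifampicin,10,27,High,DMSO (0.5%)
Acarbose,0.008,0.05,Low,DMSO (0.5%)
Ribavirin,2.6,5.2,Low,DMSO (0.5%)
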