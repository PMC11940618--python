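cell_source,drug,in_vitro_call,verified
ciPTEC,Cisplatin,positive,False
ciPTEC,Carboplatin,positive,False
ciPTEC,Canagliflozin,positive,False
ciPTEC,Dapagliflozin,negative,False
ciPTEC,Gentamicin,negative,True
ciPTEC,Streptomycin,negative,True
ciPTEC,Tenofovir,negative,False
ciPTEC,Adefovir,negative,False
ciPTEC,Telithromycin,positive,False
ciPTEC,Rifampicin,positive,False
ciPTEC,Acarbose,negative,True
ciPTEC,Ribavirin,positive,True
ciPTEC-OAT1,Cisplatin,positive,True
ciPTEC-OAT1,Carboplatin,positive,True
ciPTEC-OAT1,Canagliflozin,positive,True
ciPTEC-OAT1,Dapagliflozin,positive,True
ciPTEC-OAT1,Gentamicin,negative,True
ciPTEC-OAT1,Streptomycin,negative,True
ciPTEC-OAT1,Tenofovir,positive,True
ciPTEC-OAT1,Adefovir,positive,True
ciPTEC-OAT1,Telithromycin,positive,True
ciPTEC-OAT1,Rifampicin,positive,True
ciPTEC-OAT1,Acarbose,negative,True
ciPTEC-OAT1,Ribavirin,positive,True
TERT1,Cisplatin,positive,False
TERT1,Carboplatin,positive,False
TERT1,Canagliflozin,positive,False
TERT1,Dapagliflozin,negative,False
TERT1,Gentamicin,negative,True
TERT1,Streptomycin,negative,True
TERT1,Tenofovir,negative,False
TERT1,Adefovir,negative,False
TERT1,Telithromycin,positive,False
TERT1,Rifampicin,positive,False
TERT1,Acarbose,negative,True
TERT1,Ribavirin,negative,True
TERT1-OAT1,Cisplatin,positive,True
TERT1-OAT1,Carboplatin,positive,True
TERT1-OAT1,Canagliflozin,positive,True
TERT1-OAT1,Dapagliflozin,positive,True
TERT1-OAT1,Gentamicin,negative,True
TERT1-OAT1,Streptomycin,negative,True
TERT1-OAT1,Tenofovir,positive,True
TERT1-OAT1,Adefovir,negative,True
TERT1-OAT1,Telithromycin,positive,True
TERT1-OAT1,Rifampicin,positive,True
TERT1-OAT1,Acarbose,negative,True
TERT1-OAT1,Ribavirin,negative,True
HEK,Cisplatin,positive,False
HEK,Carboplatin,positive,False
HEK,Canagliflozin,positive,False
HEK,Dapagliflozin,negative,False
HEK,Gentamicin,negative,True
HEK,Streptomycin,negative,True
HEK,Tenofovir,negative,False
HEK,Adefovir,negative,False
HEK,Telithromycin,negative,False
HEK,Rifampicin,negative,False
HEK,Acarbose,negative,True
HEK,Ribavirin,negative,True
HEK-OAT1,Cisplatin,positive,False
HEK-OAT1,Carboplatin,positive,False
HEK-OAT1,Canagliflozin,positive,False
HEK-OAT1,Dapagliflozin,negative,False
HEK-OAT1,Gentamicin,negative,True
HEK-OAT1,Streptomycin,negative,True
HEK-OAT1,Tenofovir,negative,False
HEK-OAT1,Adefovir,negative,False
HEK-OAT1,Telithromycin,negative,False
HEK-OAT1,Rifampicin,negative,False
HEK-OAT1,Acarbose,negative,True
HEK-OAT1,Ribavirin,negative,True
Lonza340,Cisplatin,positive,False
Lonza340,Carboplatin,positive,False
Lonza340,Canagliflozin,positive,False
Lonza340,Dapagliflozin,negative,False
Lonza340,Gentamicin,negative,True
Lonza340,Streptomycin,negative,True
Lonza340,Tenofovir,negative,False
Lonza340,Adefovir,negative,False
Lonza340,Telithromycin,positive,False
Lonza340,Rifampicin,positive,False
Lonza340,Acarbose,negative,True
Lonza340,Ribavirin,negative,True
Lonza405,Cisplatin,positive,False
Lonza405,Carboplatin,positive,False
Lonza405,Canagliflozin,positive,False
Lonza405,Dapagliflozin,negative,False
Lonza405,Gentamicin,negative,True
Lonza405,Streptomycin,negative,True
Lonza405,Tenofovir,negative,False
Lonza405,Adefovir,negative,False
Lonza405,Telithromycin,positive,False
Lonza405,Rifampicin,positive,False
Lonza405,Acarbose,negative,True
Lonza405,Ribavirin,negative,True
HepG2,Cisplatin,negative,False
HepG2,Carboplatin,negative,False
HepG2,Canagliflozin,positive,False
HepG2,Dapagliflozin,negative,False
HepG2,Gentamicin,negative,True
HepG2,Streptomycin,negative,True
HepG2,Tenofovir,negative,False
HepG2,Adefovir,negative,False
HepG2,Telithromycin,negative,False
HepG2,Rifampicin,negative,False
HepG2,Acarbose,negative,True
HepG2,Ribavirin,negative,True
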