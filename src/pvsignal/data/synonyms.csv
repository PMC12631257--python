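raw,canonical
STELARA,ustekinumab
USTEKINUMAB,ustekinumab
STELARA (USTEKINUMAB),ustekinumab
REMICADE,infliximab
INFLIXIMAB,infliximab
HUMIRA,adalimumab
ADALIMUMAB,adalimumab
ENTYVIO,vedolizumab
VEDOLIZUMAB,vedolizumab
METHOTREXATE,methotrexate
PREDNISONE,prednisone
AZATHIOPRINE,azathioprine
MESALAMINE,mesalamine
IBUPROFEN,ibuprofen
LISINOPRIL,lisinopril
METFORMIN,metformin
ATORVASTATIN,atorvastatin
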