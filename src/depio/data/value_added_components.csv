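benefit,wages,social_contributions,gos,net_taxes_production
cbpa,157.38,44.50,51.66,-4.44
cbic,768.85,191.57,1277.51,52.11
in_kind,2071.40,583.69,758.64,-52.78
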