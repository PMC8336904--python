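quantity,benefit_mix,exclusive_in_kind,delta
output,10266.88,14688.01,4421.13
value_added,5900.09,8602.66,2702.57
wages,2997.63,5309.64,2312.01
social_contributions,819.76,1496.48,676.72
gos,2087.81,1932.70,-155.11
net_taxes_production,-5.11,-136.16,-131.05
jobs_total,151353,267899,116546
jobs_direct,97587,183341,85754
jobs_indirect,19816,24472,4656
jobs_induced,33950,60086,26136
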