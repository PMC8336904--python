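benefit,initial_cost,initial_cost_alt,producer_domestic_consumption
cbpa,355.42,355.42,189.62
cbic,2305.12,2305.12,2077.26
in_kind,4544.85,4545.85,2584.10
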