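benefit,direct,indirect,induced,total
cbpa,5468,691,1781,7940
cbic,20621,9550,8728,38900
in_kind,71498,9575,23441,104513
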