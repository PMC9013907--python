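precursor_mz,product_mz,collision_energy_v,role
405,359,10,quantifier
410,359,10,internal_standard
405,331,10,qualifier
405,287,10,qualifier
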