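GCF_011611525.1
GCF_014725815.1
GCF_040581375.1
GCF_040581385.1
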