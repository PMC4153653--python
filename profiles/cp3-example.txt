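# illustrative 3-cluster partition: hydrophobic / small-polar / charged
CFILMVWY;AGHNPQST;DEKR
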