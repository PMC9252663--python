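group,cured,markedly_effective,effective,ineffective
experimental,15,11,4,1
control,3,5,6,17
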