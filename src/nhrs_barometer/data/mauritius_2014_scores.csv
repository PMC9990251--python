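year,label,score
2014,overall,19.0
2014,leadership_governance,33.3
2014,developing_resources,20.83
2014,producing_utilizing,4.214
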