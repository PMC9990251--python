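year,label,score
2018,overall,44.0
2018,producing_utilizing,53.758
2018,financing,50.013
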