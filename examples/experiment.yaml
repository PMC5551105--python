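# Four-population breeding-experiment design: two long-term colonies
# (England, Belgium), one recent colony (France) and one field-derived
# population (Mauritania) whose virgin females essentially never
# produce scorable pods.  B is the lethal-equivalents load per haploid
# genome used by the mechanistic hatching simulator.
seed: 1
bootstrap: 1000
weighting: pooled
populations:
  - name: England
    B: 1.1
    n_families: 8
  - name: Belgium
    B: 3.8
    n_families: 8
  - name: France
    B: 3.9
    n_families: 7
  - name: Mauritania
    B: 3.9
    n_families: 6
    laying_prob: {outbred: 0.75, inbred_fullsib: 0.75, parthenogenetic: 0.02}
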