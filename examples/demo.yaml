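# Two-group simulated plate: regular control networks vs rarer, irregular,
# fragmenting "mutant" networks. Run:
#   meaburst run-all --config examples/demo.yaml --seed 7 --out results/demo
mode: simulate
wells_per_group: 4
seed: 7
out_dir: meaburst_out
groups:
  control:
    duration: 300.0
  mutant:
    duration: 300.0
    nb_rate: 3.0
    ibi_cov: 0.6
    frag_prob: 0.5
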