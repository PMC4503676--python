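# Segregated bait-occupancy matrix (one site-year, 3 plots x 20 baits):
#   antgrad simulate --spec examples/occupancy.yaml --out occupancy.csv
kind: occupancy
n_species: 6
n_baits: 60
occupancy_probs: [0.1, 0.15, 0.2, 0.25, 0.3, 0.4]
segregation: -0.15
seed: 7
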