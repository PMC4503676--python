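# Over-dispersed colony pattern for one 20 x 15 m plot:
#   antgrad simulate --spec examples/point_pattern.yaml --out colonies.csv
kind: point_pattern
process: hardcore
n_points: 15
plot_width: 20.0
plot_height: 15.0
min_dist: 2.0
seed: 4
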