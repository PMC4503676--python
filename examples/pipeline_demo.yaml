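# Full synthetic run over the six packaged sites (same as `antgrad pipeline --demo`):
#   antgrad pipeline --config examples/pipeline_demo.yaml --out antgrad_out
seed: 0
n_rand: 1000
stages:
- cooccurrence
- dispersion
- gradient
years:
- 2007
- 2008
output_dir: antgrad_out
exclusions:
- year: 2007
  site: Lahav
  n_plots: 2
- year: 2007
  site: Karei Deshe
  n_plots: 2
- year: 2007
  site: Ramot Menashe
  n_plots: 2
synthetic:
  plots_per_site: 3
  plot_width: 20.0
  plot_height: 15.0
  baits_per_plot: 20
  n_species: 8
  occupancy_prob: 0.2
  segregation:
    intercept: -0.12
    slope: 0.00015
  colony_density:
    intercept: 16.41
    slope: -0.011
  generalist_pattern:
    kind: hardcore
    min_dist: 2.0
  forager_loglog:
    intercept: 0.9
    slope: 0.32
  specialist:
    plot_size: 100.0
    density:
      intercept: 10.0
      slope: 0.02
    pattern:
      kind: hardcore
      min_dist: 7.0
    forager_loglog:
      intercept: 0.5
      slope: 0.55
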