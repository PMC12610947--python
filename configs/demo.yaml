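# Demonstration run: 25 simulated datasets with 8 planted driver genes,
# followed by a simulated two-stage RNAi lifespan screen of the top-ranked
# orthologs.  Driver symbols follow the screen panel's human gene names.
seed: 42
out_dir: runs/demo
deg_threshold: 0.25
rank_cutoff_pathway: 6
rank_cutoff_screen: 7
fraction_conserved: 0.7
fraction_mapped: 0.95
screen:
  min_extension_pct: 5.0
  alpha: 0.05
  n_initial: 100
  n_validation: 120
  hit_hazard_multiplier: 0.3
  censor_prob: 0.05
expression:
  n_datasets: 25
  genes_per_dataset: 3000
  samples_per_group: 5
  null_deg_rate: 0.06
  multi_probe_fraction: 0.1
  seed: 42
  drivers:
    - [EFEMP1, up, 0.6, 2.5]
    - [TMEM176A, up, 0.6, 2.5]
    - [CASP1, up, 0.6, 2.5]
    - [RSRC1, up, 0.6, 2.5]
    - [SPARC, down, 0.6, 2.5]
    - [CA4, down, 0.6, 2.5]
    - [CDC20, down, 0.6, 2.5]
    - [DIRC2, down, 0.6, 2.5]
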