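# End-to-end demo: simulate a small experiment and run every stage.
out: demo_run
seed: 42
window: 100
n_perms: 100
min_reads: 10
alpha: 0.05
min_oligos: 3
frac_unique: 0.8
max_rnas: 100
simulate:
  n_beads: 1200
  genome_length: 30000
  rna_reads_mean: 10.0
  tags_per_round: 24
  planted_sites:
    - protein: RBP1
      reference: chrS
      position: 8000
      footprint: 100
      fold: 12.0
      truncation_fraction: 0.5
    - protein: RBP2
      reference: chrS
      position: 21000
      footprint: 100
      fold: 12.0
      truncation_fraction: 0.5
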