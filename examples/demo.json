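{
  "out_dir": "scratch/demo_run",
  "seed": 11,
  "groups": ["pop1", "pop2"],
  "simulate": {
    "n_founders": 150,
    "pop_size": 600,
    "n_generations_burnin": 80,
    "split_generation": 0,
    "migration_rate": 0.5,
    "chrom_length_cM": 20.0,
    "n_variants": 2000,
    "sample_size": 100,
    "sweep": {
      "focal_variant_index": 1000,
      "selection_coefficient": 0.05,
      "sweep_start_generation": 80,
      "focal_initial_freq": 0.0033
    }
  },
  "run_qc": false,
  "ibd_min_length_cM": 0.3333,
  "ibd_seed_snps": 24
}
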