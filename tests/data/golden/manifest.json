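{
  "config": {
    "abundance": null,
    "alpha": 0.05,
    "asv_min_heavy_relab": 0.001,
    "bh_family": "per_variable",
    "counts": "fixtures/counts.tsv",
    "ef_threshold": 0.1,
    "fractions": "fixtures/fractions.tsv",
    "genus_min_heavy_relab": 0.01,
    "gradients": "fixtures/gradients.tsv",
    "heavy_window": [
      1.851,
      1.872
    ],
    "level": "genus",
    "light_window": [
      1.805,
      1.819
    ],
    "metadata": null,
    "outdir": "out",
    "policy": "max_copies",
    "predator_threshold": 94.5,
    "pseudocount": 0.5,
    "queries_fasta": null,
    "ref_taxonomy": null,
    "refs_fasta": null,
    "seed": 20230211,
    "taxonomy": null
  },
  "config_hash": "ab8a87cb7745",
  "display_floor": 0.03162277660168379,
  "groups": [
    [
      "E_coli",
      "1d"
    ],
    [
      "E_coli",
      "2d"
    ]
  ],
  "inputs": {
    "counts": "fixtures/counts.tsv",
    "fractions": "fixtures/fractions.tsv",
    "gradients": "fixtures/gradients.tsv"
  },
  "labeled_taxa": [
    "prey_E_coli",
    "t0000",
    "t0001"
  ],
  "missing_12C_groups": [],
  "n_labeled_taxa": 3,
  "outputs": {
    "ef_summary": "out/ef_summary.tsv",
    "ef_table": "out/ef_table.tsv",
    "ef_viz": "out/ef_viz.tsv"
  },
  "seed": 20230211,
  "tool": "sipscreen",
  "version": "0.1.0"
}
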