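# Full synthetic pipeline run: 2,000 cells, 8 planted clusters.
# Execute with:  cellgraph run-all configs/example.yaml
output_dir: cellgraph_out
seed: 1
simulation:
  n_cells: 2000
  n_genes: 2000
  n_clusters: 8
  doublet_rate: 0.02
  lowq_rate: 0.02
qc:
  min_umis: 600
  min_molecule_gene_ratio: 1.2
manifold:
  n_genes: 1000
  k: 100
  alpha: 1.0
clustering:
  louvain_resolution: 1.0
  min_cluster_size: 10
enrichment:
  n_shuffles: 100
trinarization:
  a: 1.5
  b: 2.0
  f: 0.2
  pep: 0.05
taxonomy:
  top_genes_per_cluster: 28
run_taxonomy_stability: false
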