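# cilicopd pipeline configuration template (`cilicopd run --config <this>`)

# Cohort manifest: YAML/JSON listing dataset_id, compartment (lung|saec),
# matrix TSV (genes x samples), metadata TSV (sample_id<TAB>group) and
# optionally scale (linear|log2; omitted = auto-detect).
manifest: study/manifest.yaml

# Either labelled source-list TSVs to merge (source, symbol, accession, name)...
geneset_sources:
  - study/geneset_sources.tsv
# ...or a pre-merged geneset TSV written by `cilicopd curate`:
# geneset: results/geneset_merged.tsv

# Source labels whose members are ciliopathy-flagged.
ciliopathy_sources: [uniprot_ciliopathy]

# Significance: raw_p calls p < alpha (default); fdr_q calls q < alpha.
alpha: 0.05
sig_rule: raw_p
t_variant: welch          # welch | student

# Common-gene table thresholds: >= table_lung_min of the lung cohorts OR
# >= table_saec_min of the SAEC cohorts.
table_lung_min: 3
table_saec_min: 2
# Cross-compartment hits: >= cross_lung_min lung AND >= cross_saec_min SAEC.
cross_lung_min: 2
cross_saec_min: 1

# Drop datasets whose fold-change sign disagrees with a gene's majority sign
# before tiering (stricter "deregulated" definition; off by default).
require_direction: false

# Optional single-cell stage: cell x gene TSV + cell annotation TSV.
# sc_matrix: sc/matrix.tsv
# sc_cells: sc/cells.tsv

outdir: results
seed: 13                  # recorded in the report for provenance
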