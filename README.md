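# cernakit

Inference of circRNA–miRNA–mRNA competing-endogenous-RNA (ceRNA) sponge
networks from two-group RNA-seq count data.

Given per-class count matrices (circRNA, miRNA, mRNA) for a two-group design
plus mature-miRNA and candidate-target sequences, the pipeline:

1. **Differential expression** (`de_analysis`) — CPM normalization, Welch's
   t (or an exact label-permutation test) on log2(CPM+1), Benjamini–Hochberg
   FDR, and class-specific significance gates (fold change ≥ 2 with raw
   p < 0.05 for circRNA/miRNA, BH q < 0.05 for mRNA, all configurable).
2. **Target prediction** (`target_prediction`) — canonical seed matching
   (6mer, 7mer-A1, 7mer-m8, 8mer) of miRNAs against circRNA/mRNA sequences,
   restricted to differentially expressed features.
3. **Network inference** (`cerna_network`) —
   - miRNA–target pairs kept when Spearman correlation < −0.7 across all
     samples (negative coexpression);
   - circRNA–mRNA pairs sharing ≥ 1 such miRNA kept when Pearson
     correlation > 0.9;
   - an upper-tail hypergeometric test on the overlap of the pair's
     miRNA-regulator sets (shared-sponge test), kept at p < 0.05;
   - assembly into a tripartite graph with every fully supported
     (circRNA, miRNA, mRNA) triad enumerated, plus ego-subnetwork extraction.
4. **Enrichment** (`enrichment`) — hypergeometric over-representation of any
   feature list against a GMT gene-set file.
5. **Synthetic data** (`synthetic_data`) — a negative-binomial generator that
   plants differentially expressed features, decoy seed matches, and true
   sponge triads driven by a latent per-sample stress factor, with ground
   truth, so the whole pipeline is verifiable offline.

All thresholds are strict inequalities. All outputs are plain text (TSV,
FASTA, GraphML, YAML, JSON) and byte-reproducible for identical inputs.

## CLI

```sh
# generate a synthetic fixture with 10 planted triads
cernakit simulate --out fixture/ --seed 1

# full pipeline from a config file
cernakit run-all --config config.yaml

# individual stages
cernakit de --counts fixture/counts_mRNA.tsv --samples fixture/samples.tsv \
    --rna-class mRNA --out de_mRNA.tsv
cernakit targets --mirna-fasta fixture/mirna.fasta \
    --target-fasta fixture/targets.fasta --out-edges edges.tsv
cernakit enrich --query query.txt --universe universe.txt \
    --gmt sets.gmt --out enrichment.tsv
```

A minimal `config.yaml`:

```yaml
counts_circ: fixture/counts_circRNA.tsv
counts_mirna: fixture/counts_miRNA.tsv
counts_mrna: fixture/counts_mRNA.tsv
samples: fixture/samples.tsv
mirna_fasta: fixture/mirna.fasta
target_fasta: fixture/targets.fasta
out_dir: results/run1
# optional overrides (defaults shown)
scc_threshold: -0.7
pcc_threshold: 0.9
sponge_p_cutoff: 0.05
min_site_type: 7mer-A1
```

`run-all` writes per-stage TSV tables, `network.graphml` (node attributes
`rna_class`, `log2fc`, `direction`; edge attributes `kind`, `coefficient`,
`sponge_p`), `triads.tsv`, and `manifest.json` with input hashes, parameters
and per-stage row counts.

## Library use

```python
from cernakit import (SimulationConfig, simulate_dataset, write_fixture,
                      PipelineConfig, run_pipeline)

dataset = simulate_dataset(SimulationConfig(seed=1))
write_fixture(dataset, "fixture/")
manifest = run_pipeline(PipelineConfig(
    counts_circ="fixture/counts_circRNA.tsv",
    counts_mirna="fixture/counts_miRNA.tsv",
    counts_mrna="fixture/counts_mRNA.tsv",
    samples="fixture/samples.tsv",
    mirna_fasta="fixture/mirna.fasta",
    target_fasta="fixture/targets.fasta",
    out_dir="results/",
))
print(manifest["stages"]["network"]["n_triads"])
```
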