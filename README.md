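# panscreen

Flag likely MAG-derived contaminant genes in pangenome-based case/control
metagenomic analyses.

When pangenome catalogs are built from metagenome-assembled genomes, a small
number of mis-binned contigs can place foreign genes inside a species'
pangenome. If the contamination source itself shifts between cases and
controls, those genes show up as strong — but spurious — associations.
`panscreen` detects differentially prevalent genes (Fisher's exact test with
a discrete false-discovery-rate adjustment), then screens the hits three
ways:

1. **Correlation lineage test** — each gene's read counts are correlated
   (Spearman) with every species' relative abundance; species are ranked by
   correlation, and the best rank whose lineage matches the gene's pangenome
   species at the family (and species) level is reported. A deep or missing
   family match flags a putative contaminant. A *conditional* variant
   restricts the correlation to samples where the gene is detected.
2. **EggNOG taxonomic-range scoring** — the gene's UHGP-90 cluster
   annotation scope is scored 1 (clearly excludes the target family),
   0 (consistent), or 0.5 (missing / too broad), driven by a user-editable
   rule table.
3. **Co-occurrence structure** — Jaccard similarity of presence/absence
   profiles per species, rendered as a clustered heatmap plus NMDS, UMAP and
   PCoA ordinations, to expose contaminant blocks from single contigs.

A separate `cluster-assoc` workflow clusters gene copy-number profiles (PAM
on Pearson correlation distance, cluster count chosen by average silhouette
width), summarizes clusters by SVD eigengenes, and tests cluster–phenotype
association (Wilcoxon rank-sum, BH adjusted) with bootstrap per-gene
t-statistics.

## CLI

```sh
# generate a synthetic community with planted contaminants (ground truth
# included); scalar overrides via a key=value file
panscreen simulate --out-dir sim/ --seed 42

# full pipeline: prevalence -> lineage test -> annotation scoring ->
# co-occurrence/ordination -> static HTML report
panscreen run \
  --species-relabund sim/species_relabund.tsv \
  --gene-reads sim/gene_reads.tsv \
  --gene-presence sim/gene_presence.tsv \
  --lineages sim/lineages.tsv \
  --metadata sim/metadata.tsv \
  --pangenome-map sim/pangenome_map.tsv \
  --out-dir out/

# recompute evaluation metrics from the packaged 86-gene labelled fixture
# (or any TSV with the same columns)
panscreen evaluate --out metrics.json

# copy-number cluster / phenotype association
panscreen cluster-assoc --gene-copynum sim/gene_copynum.tsv \
  --metadata sim/metadata.tsv --out-dir assoc/
```

All matrices are TSV in the MIDAS2 merge orientation: header row of sample
IDs, first column the feature (gene or species) ID. Annotation maps may also
be Parquet. Outputs are TSVs, a `report.html` with embedded figures, and a
`run_log.json` recording versions, seed and a config hash.

## Layout

- `src/panscreen/data_io.py` — matrix/metadata/taxonomy/annotation I/O,
  sample alignment, packaged fixture loader
- `src/panscreen/prevalence.py` — Fisher exact test, attainable p-value
  supports, discrete BH step-up adjustment
- `src/panscreen/lineage.py` — the correlation lineage test
- `src/panscreen/cooccurrence.py` — Jaccard, heatmap ordering, ordinations
- `src/panscreen/annotation.py` — EggNOG scope lookup and range scoring
- `src/panscreen/evaluation.py` — AUROC and the fixture evaluation harness
- `src/panscreen/cluster_phenotype.py` — PAM/ASW/eigengene association
- `src/panscreen/synthetic.py` — seeded community generator with planted
  contamination and full ground truth
- `src/panscreen/pipeline.py`, `cli.py`, `report.py` — orchestration, CLI,
  static report
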