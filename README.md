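# prionscape

Proteome-scale prion-like domain (PrLD) calling and downstream gene-set
statistics, with a bundled synthetic-data generator so the whole pipeline is
testable offline.

The pipeline mirrors a common in-silico survey design for prion-like
proteins:

1. **Detection** (`prld_detection`) — a two-stage caller. Stage 1 scans each
   sequence with a per-residue compositional log-likelihood ratio
   (prion-domain vs background amino-acid frequencies), calls the best
   60-residue core window and extends it greedily into a candidate domain.
   Stage 2 scores every 21-mer inside the domain with a position-weight
   matrix, rescales the best raw sum to 0–100 and accepts calls scoring
   ≥ 60.00 (configurable).
2. **Localization** (`prld_localization`) — classifies each call as
   N-terminal / internal / C-terminal under a 25/50/25 residue segmentation
   (plurality rule, ties → internal), tests the C-vs-N imbalance with a
   one-sample proportion Z-test, and builds a 20-bin start/end position
   histogram.
3. **Enrichment** (`annotation_enrichment`) — evidence-code filtering
   (IEA excluded by default), optional slim-term collapsing, two-sided
   Fisher exact tests with Bonferroni correction per namespace, and a
   log-ratio enrichment score E.
4. **Expression** (`tissue_expression`) — ordinal 0–3 coding of
   none/low/medium/high ranks, per-tissue set profiles, deviation vectors
   against a background mean, and k-means clustering (k = 3..10) with
   silhouette-based selection of k.
5. **Disease** (`disease_association`) — fraction of disease-associated
   genes vs an empirical null of 100 random same-size sets
   (95th-percentile flag, Z, empirical p).
6. **Network** (`network_analysis`) — mean degree, intra-set edges, largest
   connected component and mean shortest distance (nearest other set member
   through the full graph), each against 1000-random-set nulls.

`synthetic_data` generates every input format (FASTA proteome, annotation /
expression / disease / edge-list TSVs) with planted, recorded ground truth:
planted Q/N-rich domains with embedded amyloid cores, planted term
enrichments, planted expression clusters, planted disease-rate differences
and a planted denser network module.

## CLI

```bash
# generate a synthetic dataset with truth sidecars
prionscape simulate --preset full --seed 1 --outdir simdata

# individual stages
prionscape detect  --fasta simdata/proteome.fasta --cutoff 60.0 --out calls.tsv
prionscape localize --calls calls.tsv --fasta simdata/proteome.fasta --bins 20
prionscape enrich  --set set.txt --background bg.txt \
    --annotations simdata/annotations.tsv --exclude-evidence IEA
prionscape express --set simdata/set_genes.txt --expr simdata/expression.tsv \
    --kmin 3 --kmax 10 --seed 1
prionscape disease --set simdata/set_genes.txt \
    --background simdata/background_genes.txt \
    --diseases simdata/disease.tsv --n 100 --seed 1
prionscape network --edges simdata/edges.tsv --set simdata/set_genes.txt \
    --n 1000 --seed 1

# the full pipeline from a flat TOML config
prionscape run --config cfg.toml
```

A minimal config:

```toml
fasta = "simdata/proteome.fasta"
annotations = "simdata/annotations.tsv"
expression = "simdata/expression.tsv"
disease = "simdata/disease.tsv"
edges = "simdata/edges.tsv"
outdir = "pipe_out"
seed = 1
```

Every stage is a pure function of (inputs, config, seed); the master seed
is split into per-stage seeds with a fixed counter scheme, so reruns are
byte-identical.

## Data files

`src/prionscape/data/` ships three plain-text tables: background amino-acid
frequencies (proteome-average composition), a Q/N-rich prion-domain
composition, and a 21×20 amyloid position-weight matrix whose theoretical
min/max window sums pin the 0–100 score rescaling. All three can be
overridden on the command line (`--composition-table`, `--amyloid-matrix`).
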