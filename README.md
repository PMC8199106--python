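# rhizomics

Genome mosaicism profiling and phyletic-pattern clustering for comparative
genomics of reduced and chimeric genomes — ultra-small symbionts (CPR,
DPANN), Asgard archaea, organelles, and giant viruses, whose gene
repertoires mix sequences of several evolutionary origins and large
fractions of ORFans (genes without detectable homologs).

Instead of forcing such genomes into a single bifurcating species tree,
the package builds **rhizome** representations: every gene is attributed
an origin from the taxonomy of its best database hit, after excluding
hits from the query's own genus or taxon, and the per-genome origin
spectrum (the *mosaicism profile*) plus the bipartite gene → origin-group
network summarise the genome's reticulate history. A complementary
**phyletic-pattern** analysis clusters genomes by gene-content
presence/absence against reference gene-family sets rather than by any
single marker's phylogeny.

## Method

For each query gene, local alignments against a taxonomically labeled
reference collection are scored by affine-gap Smith–Waterman (BLOSUM62,
gap open 11 / extend 1) with Karlin–Altschul statistics
`E = K·m·n·exp(−λS)` (λ = 0.267, K = 0.041), or ingested from external
search tools in the 12-column blast tabular dialect. After self-taxon
exclusion, hits are retained at identity ≥ 20 %, query coverage ≥ 30 %,
E ≤ 10⁻³; the gene's origin is the taxonomic group of the top surviving
hit (bitscore desc, E asc, identity desc, subject id), or **ORFan** if no
hit survives. Per-genome counts `c_l` give percentages
`100·c_l/Σc_l`, rounded half-up to two decimals.

For phyletic patterns, genome *i* gets entry `x_if = 1` iff any of its
genes hits any representative of family *f* (identity ≥ 30 %, E ≤ 10⁻³).
Rows are compared by Euclidean distance — for 0/1 vectors
`d(i,j) = √Hamming(i,j)` — and clustered agglomeratively (average linkage
by default); planted-group recovery is scored by the adjusted Rand index.

A ground-truthed synthetic generator provides labeled reference
databases, mosaic genomes with planted origin proportions and donor
identity, and block-structured phyletic cohorts, so every stage is
testable end to end without downloads.

## Worked example

```bash
python analysis/01_simulate_dataset.py
python analysis/02_rhizome_profiles.py
python analysis/03_phyletic_clustering.py
```

prints

```
reference database: 70 sequences in 7 origin groups
mosaic genome: 300 genes, planted counts {'Bacteria': 162, 'CPR': 90, 'ORFan': 45, 'Archaea': 3}

attributed 300 genes; per-gene accuracy vs truth 100.00%
recovered profile (%): {'Bacteria': 54.0, 'CPR': 30.0, 'Archaea': 1.0, 'ORFan': 15.0}

60 genomes x 200 families
cut at k=5: adjusted Rand index 1.0000
```

i.e. best-hit attribution recovers the planted mosaicism (54 % bacterial,
30 % CPR, 15 % ORFan, 1 % archaeal) gene-for-gene at 90 % donor identity,
and cutting the gene-content dendrogram at the planted number of groups
reconstructs the cohort structure perfectly. Outputs (profile and
attribution tables, a Gephi-ready GEXF rhizome network, distance matrix
and Newick dendrogram) land under `results/`.

The same pipeline runs from the command line on user data:

```bash
rhizomics simulate -c config.yaml -o out/      # or bring your own FASTA
rhizomics rhizome  -c config.yaml -o out/
rhizomics phyletic -c config.yaml -o out/
```

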