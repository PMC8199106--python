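# Methods

## Best-hit origin attribution (the rhizome model)

Each gene of a query proteome is attributed one origin: the taxonomic
group (Bacteria, Archaea, DPANN, Asgard, Eukaryota, CPR, Viruses,
Mitochondria, Chloroplast — configurable) of its top-scoring reference
hit after self-taxon exclusion and threshold filtering, or the
distinguished label **ORFan** if nothing survives. The model makes three
assumptions worth stating plainly: (i) the best surviving local-alignment
hit is an adequate proxy for a gene's closest relative — no per-gene tree
is built, and the method cannot orient a transfer (donor vs acceptor);
(ii) an ORFan is defined *relative to the supplied database and
thresholds*, not as an absolute claim of novelty; (iii) one origin per
gene — the top-1 rule — because the genome-wide figure the profile feeds
draws one curve per gene. Top-k majority voting exists as an option but
is off by default.

Self-exclusion removes hits from the query's own taxon ids and, at the
default `genus` rank, from its genus; a `group` rank is available but
would erase within-group transfer signal, which is exactly what CPR-vs-CPR
or virus-vs-virus attribution is meant to show.

### Alignment scoring

The built-in aligner is affine-gap Smith–Waterman (a gap of length L
costs open + L·extend) under BLOSUM62 with gap open 11 / extend 1 — the
conventional protein-search defaults. The ambiguity residue X scores 0
against everything (BLOSUM62's small negative X scores would let long
X-runs accumulate signal). Identity is identities / alignment columns
(gap columns included), coverage is aligned query span / query length —
query-side, so ORFan calling depends on the gene, not the subject.
Significance uses the Karlin–Altschul form E = K·m·n·exp(−λS) with the
published gapped-BLOSUM62 constants λ = 0.267, K = 0.041, n = total
database residues; the bitscore is (λS − ln K)/ln 2. When hits are
ingested from an external search tool (12-column tabular format) the
tool's own E-values and bitscores are used unchanged and coverage is
reconstructed from the query span.

Two numerical details: if no residue pair scores positive the optimal
local alignment is empty and a zero-width result (score 0, length 0) is
returned, which fails any meaningful threshold set; and database search
skips the traceback for subjects whose optimal score cannot reach the
E-value cutoff (E is strictly decreasing in score), which is
result-identical to aligning and filtering every pair — the test suite
checks this equivalence against an exhaustive oracle.

### Thresholds

Three named bundles, applied inclusively (≥ / ≤):

| bundle   | identity | coverage | E-value | length | use |
|----------|---------:|---------:|--------:|-------:|-----|
| rhizome  | 20 %     | 30 %     | 10⁻³    | —      | origin attribution |
| phyletic | 30 %     | —        | 10⁻³    | —      | family-presence detection |
| marker   | 20 %     | —        | 10⁻³    | 70 aa  | conserved-marker retrieval |

An E-value cutoff is a *rate*, not a wall: by construction it admits
about `max_evalue` random hits per query even with perfectly calibrated
statistics. At E ≤ 10⁻³ a genome with hundreds of true ORFans will
therefore occasionally (order 10⁻³ per ORFan; measured ≈ 1.7·10⁻³ on the
synthetic null, where the published constants are only approximate for a
uniform residue background) attribute one to an origin group. This is a
property of best-hit attribution itself, not an implementation artifact,
and it bounds how exactly planted compositions can be recovered.

### Profiles, shares, networks

Counts per label are converted to percentages with exact integer-ratio
arithmetic rounded half-up to two decimals (506/935 → 54.12). Combined
shares (e.g. "own" sequences = own-group + ORFan) are computed from
summed counts before the single rounding step, so 282+142 of 935 gives
45.35 exactly rather than a drifted sum of two rounded shares. Profiles
are compared by total-variation distance on the percentage scale (0 =
identical composition, 100 = disjoint). The rhizome network is a
bipartite directed graph, gene → origin group, edge weight = best-hit
identity; ORFans are isolated gene nodes. Export is GEXF 1.2 for
Gephi-class tools.

## Phyletic-pattern clustering

Genome × family presence/absence: entry 1 iff ≥ 1 gene hits ≥ 1 family
representative at the phyletic thresholds ("at least one ortholog" taken
literally; multi-copy families are not distinguished). Detection is
one-way best-hit against representatives — a deliberate desk-scale
choice; reciprocal-best verification would need the full proteome pair
and is out of scope. All-zero columns are retained: absence everywhere is
itself a character. Distances are Euclidean (√Hamming for 0/1 rows);
clustering is scipy agglomerative with average linkage by default —
the classical choice for gene-content matrices and robust to block
noise; single/complete/weighted/ward are accepted. scipy's
nearest-neighbor-chain implementation is deterministic for a given
input, which is the property that matters for reproducibility; its
internal tie handling is its own. Partition agreement with a reference
labeling is scored by the adjusted Rand index, chosen because the claim
being tested is a partition topology, not branch lengths. `cut_tree`
produces exactly k clusters; with duplicated genomes (zero-height
merges) some k values are degenerate, as for any ultrametric cut.

Newick export writes leaf labels = genome ids and ultrametric branch
lengths (parent merge height − child height), so a two-leaf dendrogram
merging at height h renders as `(A:h,B:h);`.

## Synthetic data: what it emulates, what it does not

The generator plants the structures the pipeline is supposed to recover:

- **Reference database** — random proteins (uniform over the 20 standard
  residues — the simplest null; a composition table can be supplied) in
  2+ origin groups, one taxon and genus per group, default 7 groups × 10
  sequences of 100–200 aa. Sizes are the package's desk-scale choice:
  large enough that E-value screening and group competition are real,
  small enough that a 935-gene genome attributes in seconds.
- **Mosaic genomes** — each gene is either a point-mutated copy of a
  uniformly drawn donor from its assigned group (i.i.d. substitutions at
  rate 1 − identity_target, replacement drawn from the 19 other
  residues; no indels, so coverage stays at 100 % and identity is the
  binding constraint) or, for the ORFan fraction, a fresh random
  sequence. Proportions are apportioned to integer counts by largest
  remainder (ties to the earlier label), making planted counts exact and
  deterministic.
- **Phyletic cohorts** — families split into group-characteristic
  blocks; presence Bernoulli(0.9) in a genome's own block, 0.05
  elsewhere, 5 groups × 12 genomes × 200 families by default.

All generators are pure functions of spec + seed: reruns are
byte-identical. What the generator does *not* emulate: phylogenetic
correlation between groups (no trees, no rate matrices), realistic
residue composition, indels, paralogy, or genome-size heterogeneity.
Passing recovery tests therefore shows the attribution and clustering
machinery is correct under planted truth, not that real databases are
this clean — in real use the reference's taxonomic labeling and
completeness dominate the error budget.

## Design choices that were genuinely open

- "Same genus or taxon" exclusion is rank-configurable (default genus,
  own taxon ids always excluded) since either reading is defensible.
- Average linkage default: the clustering tool used for such dendrograms
  offers several linkages without a canonical choice; average is the
  conventional default for phyletic patterns.
- Percentages round half-up, not banker's, to match how such tables are
  conventionally printed.
- The mosaicism profile is computed over all genes of the genome (not
  only genes with pre-exclusion hits).
- "±" in combined shares is read as summation (30.16 + 15.19 = 45.35 is
  exact).

## Problem sizes and limitations

Default validation sizes — 935-gene genomes against a 70-sequence
database, 60-genome phyletic cohorts — run the full suite in about two
minutes on one core. The built-in aligner is exact but quadratic per
pair: for real proteome-vs-database scale, run an external heuristic
search and ingest its tabular output, which the pipeline treats
identically downstream. Known limitations: no composition-based score
adjustment (the classical guard against the low-complexity false hits
discussed above), no transfer directionality, and ortholog detection
without reciprocity can over-call presence for promiscuous families.
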