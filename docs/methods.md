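# Methods

`seedregnet` models a common design in plant multi-omics: a short seed
development time course (four stages T1–T4, roughly 21–63 days after
flowering, four biological replicates each) profiled with both bulk
RNA-seq and a seed metabolome, plus four mature tissues (flower, leaf,
root, stem; three replicates) sequenced to sharpen transcription-factor
(TF) / target relationships. The pipeline asks two questions: which
temporal co-accumulation clusters structure the transcriptome and
metabolome, and which TFs plausibly regulate the structural genes of a
biosynthesis pathway — here modelled on the dihydroxy fatty-acid
(diOH-FA) pathway of *Orychophragmus violaceus* (FAD2, FAE1, KCR, HACD,
ECR, plus DGAT for storage).

## Quantification and filtering

Counts are converted to transcripts per million per sample:
`rate_g = count_g / length_kb_g`, `TPM_g = 1e6 * rate_g / Σ rates`.
Gene length is the summed exon length (union counting). Non-degenerate
TPM columns therefore sum to exactly 1e6; all-zero columns are left at
zero rather than producing NaNs. A gene is called *expressed* when its
TPM is strictly greater than 3 in at least one sample; the strict
inequality matters only at the boundary but is pinned by a test because
it changes the expressed-gene count. Heatmap-style standardisation is
per-feature z-scoring with the sample (n−1) standard deviation;
zero-variance rows are defined to map to zero, and an optional clip
truncates to ±4 (cluster panels) or ±2 (pathway panels).

## Temporal co-clustering

Clustering operates on **group-mean, z-scored profiles** (one value per
stage), not per-sample values: the scientific object is the stage
pattern, and replicate noise would otherwise dominate the distance.
K-means uses Lloyd's algorithm with k-means++ seeding, `n_init = 10`
restarts scored by total within-cluster sum of squares, and a fixed
RNG seed; assignment ties break toward the lowest cluster index so a
given seed is fully reproducible. `k = 3` by default — the three
temporal archetypes (early / mid / late peak) — with no automatic k
selection. Cluster labels are renumbered by centroid peak position:
cluster 1 peaks at the last stage, cluster 3 at the first. Gene and
metabolite matrices are clustered separately and matched afterwards by
maximum-total-Pearson assignment of centroids (Hungarian algorithm),
which makes the cross-omics correspondence explicit rather than visual.

PCA centers features and reports variance fractions from the singular
values (they sum to 1 by construction); HCA supports complete or
average linkage on Euclidean or 1−Pearson distances and emits the merge
tree as newick.

## Promoters and binding sites

The promoter is the 2,000 bp upstream of the transcription start site,
approximated by the gene's 5′ end (one transcript per gene in generated
annotations; with several mRNAs the 5′-most start is used). Plus-strand
genes starting at s take GFF positions [max(1, s−2000), s−1];
minus-strand genes ending at e take [e+1, e+2000] reverse-complemented,
so every promoter reads 5′→3′ relative to its gene. Promoters truncated
by a contig edge are flagged; overlap with upstream genes is not
masked.

Binding sites are predicted with a log2-odds PWM scan: counts are
smoothed with pseudocount 0.25, compared against a uniform background,
and every window on both strands is scored. A window is a hit when its
*relative score* — position between the matrix's minimum and maximum
attainable scores — reaches 0.85. Windows containing N are unscorable.
The original analyses behind this design used a web service whose
settings are not recoverable; the log-odds scan is this package's own
explicit, deterministic operationalisation, and its exact agreement
with a brute-force all-windows scorer is part of the test suite. The
presence map (TF × gene, binary) is the structural evidence consumed by
network inference; raising the threshold can only remove presences.

## Network inference

An edge TF → structural gene requires three coinciding pieces of
evidence: Pearson correlation above the threshold, a two-sided p-value
below 0.05 from the Student-t transform `t = r·sqrt((n−2)/(1−r²))`, and
a predicted binding site in the target's promoter. Two regimes mirror
the two analyses the design supports:

* **cluster_seed** — correlations over the 16 seed samples at sample
  level, r > 0.95, candidates restricted to TF/gene pairs in the same
  temporal cluster;
* **multi_tissue** — correlations of group means over the 8 groups
  (4 stages + 4 tissues, n = 8), r > 0.8, no cluster constraint.

The threshold applies to *signed* r, so strong negative correlations
are not edges. No multiple-testing correction is applied to edge
p-values — a deliberate mirror of common practice in correlation
networks and a documented caveat, since at genome scale the raw p<0.05
cut-off admits many chance correlations; the binding-site constraint is
what keeps the synthetic false-positive rate near zero. Constant
expression vectors cannot be tested and are skipped with a log entry.
Sub-networks keep every edge touching a focal gene; family summaries
count distinct edge-bearing TFs per family. Export formats are SIF
(`TF regulates GENE`), GraphML with edge/node attributes, and an edge
TSV that round-trips exactly.

## Enrichment

Pathway over-representation is the one-sided upper-tail hypergeometric
test `P(X ≥ overlap)` with N = |universe|, K = |set ∩ universe|,
n = |cluster|, followed by Benjamini–Hochberg FDR across tested sets.
The universe defaults to the expressed genes (post TPM filter), the
standard background for co-expression panels — not the whole genome,
which would inflate significance.

## Orthogroup utilities

Gene trees carry `species|gene` leaves and a focal-clade species set
(Brassicaceae in the motivating study). Splitting returns every maximal
subtree whose leaves are all in-clade; the outputs partition the
in-clade leaves and are fixed points of re-splitting. Unrooted inputs
are midpoint-rooted first (a convention; the upstream rooting is not
recoverable). The topology filter is this package's explicit
operationalisation of "filter by tree topology": a subtree passes when
it holds at least `min_species` species and every species-informative
bipartition (edges whose two sides share no species after collapsing
within-species duplicates) occurs in the species tree restricted to the
same species; violated bipartitions are reported. Copy numbers are leaf
counts per species per retained subtree. Gene-family membership is the
exact intersection of a domain-scan hit list and a similarity-search
hit list, consumed as plain id sets.

## The synthetic study

The generator is the package's test bed: it emulates the study design
and plants structure that every downstream stage must recover.

* **Archetypes.** Stage profiles are fixed unit-norm vectors over
  (T1..T4): early (1, .4, .1, 0), mid (.1, 1, .9, .2), late
  (0, .2, .5, 1), scaled by an amplitude of 1.0 on the natural-log
  scale; each archetype also has fixed modest tissue baselines so the
  8-group regime has signal. Genes and metabolites are assigned
  archetypes round-robin.
* **Counts.** Expected log-abundance is baseline (uniform log 100–2000)
  plus the archetype profile; replicate noise is multiplicative
  log-normal with sd 0.25, and integer counts are Poisson draws around
  the resulting mean. A debug path (sd 0, Poisson off) produces exact
  replicate copies for closure tests.
* **Planted edges.** By default 20 TF → gene pairs (30 TFs among 300
  genes), each sharing its archetype and a latent Gaussian factor with
  loading sqrt(0.98) inside the noise term, so the pair stays
  correlated above the network threshold while non-regulated pairs
  share no latent component. Decoy pairs of the same archetype still
  correlate through the shared stage profile — as real co-expressed
  genes do — which is exactly why the binding-site constraint, not the
  correlation threshold, carries the precision of the inference.
* **Genome.** Uniform-random contigs with non-overlapping
  [promoter][gene] blocks on alternating strands, one mRNA per gene.
  Each TF gets a sharp consensus PWM (width 10; consensi pairwise
  Hamming ≥ 3 apart including reverse complements); each regulated
  gene's promoter receives its regulator's consensus at a random
  offset, half reverse-complemented. All other promoter windows are
  then *scrubbed*: chance hits of any non-regulator motif above the
  scan threshold are re-randomised (planted placements are protected),
  so the presence map equals the planted edge set exactly. The uniform
  background makes the chance-hit rate analytically small, which keeps
  scrubbing cheap.
* **Metabolome.** Seed samples only (tissue samples are rejected), with
  class labels drawn from the eleven-class vocabulary at the published
  class frequencies.

Everything derives from one integer seed through independent
substreams, so a configuration reproduces byte-identical fixture
bundles. What the generator does **not** emulate: sequencing reads and
mapping artefacts, isoform structure, mass-spectrometry peak shapes,
batch effects, and realistic promoter composition (GC bias, repeats).
Passing recovery tests therefore demonstrates the correctness and
calibration of the pipeline's logic under its stated noise model, not
performance on real tissue data.

## Problem sizes and numerical choices

Recovery suites run the default study (300 genes / 30 TFs / 20 edges /
16 seed samples) across 20 generator seeds; the small fixture used by
unit tests is 40 genes / 6 TFs. Scanning is vectorised over promoters;
the scrubbing pass uses float32 scoring with a conservative margin
(anything within 1e-4 of the threshold is rewritten) so that the exact
float64 scan can never find a hit the scrub missed. K-means tolerance
is 1e-6 on the WSS decrease; |r| = 1 returns p = 0 exactly; BH FDR
values are clipped to (0, 1]. Empty k-means clusters re-seed from the
point farthest from its centroid, lowest index first.

## Known limitations

* Binding-site calls are sequence-only; no chromatin or ChIP evidence.
* Edge p-values are uncorrected (see above) and correlation is not
  causality; edges are hypotheses for validation.
* The topology filter and rooting conventions are explicit choices
  where the upstream methods were under-specified; results should be
  read relative to those conventions.
* The expression filter operates on sample-level TPM; filtering on
  replicate means would admit a slightly different gene set.
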