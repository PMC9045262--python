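# Methods

`sdpmark` implements a pipeline for resolving bacterial communities below the
phylotype level: it delineates sequence-discrete populations (SDPs) from
genome-wide average nucleotide identity (gANI), screens single-copy
protein-coding genes for short amplicons able to discriminate those SDPs, and
quantifies SDP composition from barcoded marker-gene amplicon sequencing
(MGAS). The stages are independent library functions; the synthetic-community
generator ties them together for end-to-end validation.

## SDP delineation

Input is a symmetric percent-identity matrix over genomes. ANIb-style
estimates are directional, so on ingest the two directions are averaged into
one pairwise gANI value and the diagonal forced to 100. Genomes are
partitioned as **connected components of the graph with an edge wherever
gANI ≥ t**, with t = 95% by default and ties at exactly t merged. Components
are labelled `SDP_1 … SDP_k` in decreasing size (ties broken by the
lexicographically smallest member), so the labelling is deterministic and
permutation-invariant.

The delineation rule is often phrased on clades of a core-genome tree. The
graph formulation is tree-free and coincides with the clade reading whenever
inter-SDP identity sits uniformly below the threshold — the regime observed
for honeybee gut phylotypes, where cross-SDP gANI is typically near 80%.
Rather than assuming that regime, `partition_vs_tree` checks it: each SDP is
tested for monophyly on the (unrooted) reference tree via bipartitions, and
for a non-monophyletic SDP the bipartition side maximizing (members inside −
intruders) is taken as its core; members outside the core are reported as
misplaced, attributed to the majority SDP of the nearest enclosing clade's
other tips. In a fully symmetric interleaving no individual leaf can be
blamed, and only the per-SDP monophyly flags are set.

## Entropy screening

Per-column Shannon entropy of a cross-genome alignment is computed in bits.
Two gap conventions are supported: `include_gap` (the default, counting `-`
as a fifth character, as oligotyping does) and `ignore_gap` (renormalizing
over A/C/G/T). `N` is never counted; a column with nothing countable scores 0
with a warning. The average Shannon entropy (ASE) summarizes a gene, and can
be recomputed on row subsets to compare phylotype-level with per-SDP
variation. Windowed means use a 20-column window sliding in 5-column steps;
trailing columns not covered by a full window are dropped.

Region calling operationalizes the visual "conserved flank / hypervariable
core" pattern with two declared thresholds (both exposed as parameters):

* **conserved** — a maximal run of columns with per-site entropy ≤ 0.2 bits
  and length ≥ 17 columns (the length of the shortest primer in the published
  assay, so a conserved call can always host a primer);
* **hypervariable** — the union of windows whose mean exceeds the gene-wide
  mean entropy; overlaps with conserved calls are resolved in favour of
  conserved.

Amplicon candidates are ordered pairs of conserved regions enclosing at least
one hypervariable call, with ungapped length (measured on the first alignment
row, primer sites included) within 150–550 bp. Each candidate carries the
mean cross-SDP divergence of its enclosed core, and candidates are ranked by
that divergence. A gene with no conserved flanks, or no hypervariable core,
yields an empty list — that is the rejection path, not an error.

In-silico PCR uses Hamming matching (no indels) of IUPAC primers with at most
2 mismatches and the 3 terminal 3′ bases exact — standard practice for
primer-specificity checks; the reverse primer is matched through its reverse
complement, whose leftmost template base is its 3′ end. All (forward,
reverse) site pairs in productive orientation are reported with the primer
footprints included in the product, so the published frr pair on its
reference template yields a 206-bp product.

Cross-SDP similarity of a region is the mean ± SD percent identity over all
cross-SDP row pairs, computed on columns where both rows are non-gap (N
excluded). SD is the sample SD (ddof = 1).

## Marker-gene concordance

A candidate gene must reproduce the SDP partition on its own tree. Trees are
built by neighbor joining (scikit-bio) on p-distances — the proportion of
differing sites over mutually non-gap, non-N columns — with an optional
Jukes–Cantor transform d = −(3/4)·ln(1 − 4p/3) (p ≥ 0.75 is an error). NJ
replaces likelihood inference deliberately: the concordance test needs only
topology, NJ recovers it exactly on additive distances, and the property is
tested against generated topologies. Misplaced strains are reported with the
mean identity between the confused SDPs, since low inter-SDP divergence is
the usual cause of such confusions.

## MGAS quantification

* **Demultiplexing** assigns a read to a sample iff its first 6 nt exactly
  match the sample's forward or reverse barcode; reverse-barcode hits are
  reverse-complemented into amplicon orientation and all barcodes are
  trimmed. Assigned + unassigned always equals the input count; colliding
  barcodes in the sheet are an error.
* **Dereplication** collapses identical sequences into features ordered by
  total abundance (ties lexicographic). This replaces model-based denoising:
  with the synthetic error profile (≤ 1% substitutions) the 97% classifier
  absorbs sequencing error, and denoising proper is third-party computation
  outside this package's scope.
* **Classification** aligns each feature globally (edlib) against every
  reference amplicon. Identity is matches / alignment columns after stripping
  terminal indel runs (the "blast identity" dialect for near-full-length
  hits). Hits below 0.97 are dropped; among hits within 0.005 of the best,
  the SDP is assigned only by consensus, else the feature is `UNASSIGNED`.
* **Abundance**: RA_SDP = NR_SDP / NR_assigned × 100 per sample, over
  assigned reads only; the unassigned fraction is reported separately, and a
  sample with nothing assigned is flagged rather than NaN-propagated.
* **Filtering** zeroes per-sample feature counts < 100 (strict), per sample,
  before interpretation; features empty everywhere are dropped.
* **OTU clustering** (for threshold-based comparisons at 97%/99%) is greedy
  centroid clustering in abundance order; the greedy result is order-defined
  and documented as such, not claimed optimal.

**Rarefaction** subsamples a sample's reads without replacement
(multivariate hypergeometric) at each depth, `reps` times; detection means
≥ 1 read (configurable) of the SDP. A with-replacement (multinomial) mode
exists because it admits closed-form validation: a member at fraction f is
detected with probability 1 − (1−f)^n, so a 1% member needs
⌈ln 0.05 / ln 0.99⌉ = 299 reads for 95% detection. `min_reads_for_detection`
returns the smallest evaluated depth reaching a target probability (default
95%), replacing by-eye curve reading with a stated rule.

**Repeatability** is ICC(C,1) — two-way mixed model, consistency,
single-measurement unit: (MS_BS − MS_E) / (MS_BS + (k−1)·MS_E) from the
two-way ANOVA without interaction. Computed directly from the mean squares
(and cross-checked against pingouin's ICC(C,1) in the test suite); a
zero-variance matrix yields NaN with a warning.

**Diversity**: Shannon H′ = −Σ p ln p (natural log), Bray–Curtis
dissimilarity, and classical-scaling PCoA (scikit-bio) with the eigenvalue
spectrum returned.

## Synthetic communities

The generator's defaults are the study conditions, not tuning knobs:

* Gene families evolve a random root sequence on a balanced tree — one
  ancestor per SDP, strains below it — under a Jukes–Cantor model (Poisson(d)
  hits/site/branch, uniform over the 3 alternative bases). The divergence
  parameters are expected substitutions/site *separating* two lineages
  (half per branch): `inter_sdp_divergence = 0.09` gives cross-SDP identity
  1/4 + 3/4·e^(−4·0.10/3) ≈ 90.6%, the ≈ 91% regime the published frr marker
  shows between SDPs; `intra_sdp_divergence = 0.01` keeps within-SDP identity
  ≈ 99.3%, inside the < 5% intra-SDP bound and above the 97% classification
  threshold. Conserved flanks (17 columns per side by default) are held
  invariant so the screen can find primer sites; disabling them produces the
  negative-control gene.
* ANI matrices draw intra-SDP values in [96, 99.5] and inter-SDP values in
  [77, 83], reproducing the clean discontinuity around the 95% rule.
* Mock panels follow the published design: 24 communities over five SDPs —
  all five equal, five leave-one-out quartets, five trios, and a graded
  series taking one member from 50% down to 0.02% — sequenced as multinomial
  draws at a chosen depth with per-base substitution errors, random strand
  orientation, and per-sample 6-bp barcodes. A truth log accompanies every
  batch.

What the generator does **not** emulate: quality-score-correlated errors,
indels, chimeras, PCR amplification bias, copy-number variation, or
alignment uncertainty (simulated families are gap-free and aligned by
construction). Passing the end-to-end tests therefore demonstrates the
correctness of the bookkeeping, classification and statistics under
multinomial sampling noise — not robustness to every artifact of real
sequencing runs, which is what the mock-community experiments in a wet lab
are for.

## Numerical and design choices

* Entropy is reported in bits; magnitudes of windowed profiles then sit in
  [0, log2 5] with gaps counted.
* Coordinates are 0-based half-open alignment columns everywhere; amplicon
  lengths are reported ungapped on the first alignment row.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic function takes an explicit seed and records it in its result
  where a result object exists.
* Deterministic orderings throughout: SDP labels by size then member id;
  features by abundance then sequence; OTU centroids in visiting order.
* Scale of the validation runs: the mixture-recovery check uses 24 mixtures
  × 80,000 reads (error-free), replicate ICC uses 3 × 20,000-read runs, and
  oracle checks use hundreds of small random instances — sizes chosen so the
  whole suite completes in minutes on one CPU while keeping the rarest
  member (0.02%) at an expected 16 reads, comfortably detectable.

## Known limitations

* The delineation rule is genuinely graph-based; if a dataset violated the
  ANI-discontinuity regime (chained components straddling 95%), the clade
  reading and the graph reading could differ — the tree concordance check
  surfaces this instead of hiding it.
* Classification assumes references cover the community; novel SDPs appear
  only as `UNASSIGNED` mass.
* Greedy OTU clustering depends on abundance order, as in the de-novo
  clustering tools it mirrors.
* In-silico PCR models substitution mismatches only; primers with indels
  relative to the template are not matched.
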