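# sdpmark

Marker-gene screening and quantification of **sequence-discrete populations
(SDPs)** — the strain-level lineages inside a bacterial phylotype that 16S
amplicons cannot tell apart.

Gut communities of social bees (and many other host-associated microbiomes)
are dominated by a handful of phylotypes, each composed of several SDPs with
distinct ecology. SDPs separate cleanly at the genome level: within an SDP,
genome-wide average nucleotide identity (gANI) is high, while between SDPs it
drops far below 95%. `sdpmark` turns that discontinuity into a practical
assay:

1. **Delineate** SDPs from a pairwise gANI matrix: connected components of
   the graph with an edge wherever gANI ≥ 95% (`delineate_sdps`), verified
   against a reference phylogeny by monophyly testing (`partition_vs_tree`).
2. **Screen** single-copy protein-coding genes for discriminating amplicons
   using per-site Shannon entropy: a usable marker has conserved flanks
   (≤ 0.2 bits/site over ≥ 17 columns) around a hypervariable core
   (20-bp windows above the gene mean), with an amplicon of 150–550 bp
   (`screen_gene`, `in_silico_pcr` with published primer pairs such as
   `FRR_PRIMERS`).
3. **Check concordance**: a marker's neighbor-joining gene tree must keep
   every SDP monophyletic (`marker_concordance`); misplaced strains are
   reported with the inter-SDP similarity that explains them.
4. **Quantify** composition from barcoded marker-gene amplicon sequencing
   (MGAS): demultiplex on inline 6-bp barcodes, dereplicate, classify
   features against reference amplicons at 97% identity with a consensus
   rule, and report

   RA_SDP = NR_SDP / NR_assigned × 100,

   plus detection limits by rarefaction, repeatability by ICC(C,1), and
   Shannon/Bray-Curtis/PCoA community summaries.
5. **Simulate** everything needed to validate the pipeline end to end:
   SDP-structured gene families, ANI matrices, and 24-sample mock panels
   with members spanning 0.02%–50% (`sdpmark.simulate`).

## Worked example

Simulate a five-SDP mock panel and quantify it (`examples/04_mock_quantification.py`):

```python
import sdpmark as sm

aln, part, _ = sm.simulate_gene_family(sm.SimSpec(seed=42))
amps  = sm.representative_amplicons(aln, part)
sheet = sm.make_sample_sheet(sm.default_mock_design(part.sdps), seed=42)
batch, _ = sm.simulate_mock_reads(amps, sheet, depth=20_000, seed=42)

by_sample, unassigned = sm.demultiplex(batch, sheet)
features = sm.dereplicate(by_sample)
refs  = [sm.GeneRecord(f"{s}_rep", q, sdp=s) for s, q in amps.items()]
table = sm.abundance(features, sm.classify(features, refs))
print(table.relative.loc["M02"].round(3))
```

Output (sample M02 is a leave-one-out quartet, 25% each):

```
SDP_1     0.000
SDP_2    24.690
SDP_3    25.115
SDP_4    25.135
SDP_5    25.060
Name: M02, dtype: float64
```

The absent member is reported at zero and the four present members are
recovered at 25% up to multinomial sampling noise.
Across the whole 24-sample panel the log-scale squared correlation between
estimated and true relative abundance is 0.994 at this depth (printed by the
example), and ~0.9999 at a depth of 80,000.

The other examples each exercise one capability: `01` SDP delineation and a
threshold sweep, `02` the entropy screen accepting a marker-like gene and
rejecting an invariant one, `03` tree concordance flagging swapped strains,
`05` rarefaction detection limits (a 1% member needs ~299 reads for 95%
detection), ICC repeatability and diversity summaries.

A thin CLI wraps the same functions for shell use:

```bash
sdpmark simulate --seed 7 -o fixtures/
sdpmark delineate --ani fixtures/ani.tsv --threshold 95 -o partition.tsv
sdpmark screen --aln fixtures/gene.aln.fasta --partition fixtures/partition.tsv
sdpmark quantify --reads fixtures/reads.fasta --samples fixtures/samples.tsv \
    --refdb fixtures/amplicons.fasta --partition fixtures/partition.tsv -o out/
```

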