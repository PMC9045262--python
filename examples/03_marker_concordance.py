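"""Test whether a marker gene reproduces the reference SDP phylogeny.

A marker is only trustworthy for placement if its gene tree keeps every SDP
monophyletic.  We build a neighbor-joining tree from pairwise distances and
check it against the partition; then we corrupt the alignment by swapping
two strains' sequences across SDPs and show the check flags exactly those
strains, with the inter-SDP similarity context that explains the confusion.
"""

import sdpmark as sm

aln, part, _ = sm.simulate_gene_family(sm.SimSpec(seed=4))

report, tree = sm.marker_concordance(aln, part)
print(f"intact gene concordant: {report.is_concordant}")

rows = dict(zip(aln.row_ids, aln.rows))
rows["SDP_1.s1"], rows["SDP_2.s1"] = rows["SDP_2.s1"], rows["SDP_1.s1"]
swapped = sm.MultipleAlignment(aln.gene_name, list(rows), list(rows.values()))

report, _ = sm.marker_concordance(swapped, part)
print(f"after swapping two strains across SDPs, concordant: {report.is_concordant}")
for leaf, expected, observed in report.misplaced:
    sim = report.similarity_context.get(leaf, float("nan"))
    print(
        f"  {leaf}: expected {expected}, observed in {observed} "
        f"(inter-SDP identity {sim:.2f}%)"
    )
# The flagged strains are exactly the two whose sequences were swapped; a
# gene whose SDPs are this well separated (~90% identity) only misplaces
# strains when the data themselves are mislabelled.
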