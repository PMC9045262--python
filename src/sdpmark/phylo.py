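"""Distance-based marker-gene trees and SDP concordance testing.

A candidate marker must reproduce the reference SDP phylogeny: its gene tree,
built here by neighbor joining on pairwise p-distances (optionally
Jukes-Cantor corrected), must keep every SDP monophyletic.  Strains that land
inside a foreign SDP's clade are reported together with the inter-SDP
similarity context that usually explains the confusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode
from skbio.tree import nj

from .delineate import ConcordanceReport, SdpPartition, partition_vs_tree
from .entropy import inter_sdp_similarity
from .refdb import MultipleAlignment


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if (np.diag(self.values) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < 0).any() or not np.isfinite(self.values).all():
            raise ValueError("distances must be finite and non-negative")


def pdistance(aln: MultipleAlignment, jukes_cantor: bool = False) -> DistanceMatrix:
    """Pairwise proportion of differing sites over mutually non-gap columns.

    Columns where either row holds '-' or 'N' are excluded from the
    comparison.  With ``jukes_cantor`` the p-distance is transformed to
    d = −(3/4)·ln(1 − (4/3)p); p ≥ 0.75 is then an error (the correction
    diverges).
    """
    n = aln.n_rows
    vals = np.zeros((n, n))
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
    masks = [(r != b"-") & (r != b"N") for r in rows]
    for i, j in combinations(range(n), 2):
        both = masks[i] & masks[j]
        comp = int(both.sum())
        if comp == 0:
            p = 0.0
        else:
            p = float((rows[i][both] != rows[j][both]).sum()) / comp
        if jukes_cantor:
            if p >= 0.75:
                raise ValueError(
                    f"p-distance {p:.3f} between {aln.row_ids[i]} and "
                    f"{aln.row_ids[j]} is >= 0.75; Jukes-Cantor undefined"
                )
            p = -0.75 * np.log1p(-4.0 * p / 3.0)
        vals[i, j] = vals[j, i] = p
    return DistanceMatrix(list(aln.row_ids), vals)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted; ≥ 3 taxa required)."""
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return nj(SkbioDistanceMatrix(dm.values, dm.ids))


def marker_concordance(
    gene_aln: MultipleAlignment,
    partition: SdpPartition,
    jukes_cantor: bool = False,
) -> tuple[ConcordanceReport, TreeNode]:
    """Does this gene's NJ tree keep every SDP monophyletic?

    Composes pdistance → nj_tree → partition_vs_tree.  For each misplaced
    strain the report carries the mean percent identity between its expected
    SDP and the SDP it was observed in — low inter-SDP divergence is the
    usual cause of such confusions.
    """
    dm = pdistance(gene_aln, jukes_cantor=jukes_cantor)
    if len(dm.ids) < 3 or len(partition.sdps) < 2:
        # too small to misplace anything: trivially concordant
        present = {partition.labels[r] for r in gene_aln.row_ids}
        return (
            ConcordanceReport(True, {s: True for s in present}),
            None if len(dm.ids) < 3 else nj_tree(dm),
        )
    tree = nj_tree(dm)
    report = partition_vs_tree(tree, partition)
    for leaf, expected, observed in report.misplaced:
        if observed in partition.sdps:
            pair_rows = [
                r
                for r in gene_aln.row_ids
                if partition.labels[r] in (expected, observed)
            ]
            sub = gene_aln.subset_rows(pair_rows)
            sim = inter_sdp_similarity(
                sub, SdpPartition({r: partition.labels[r] for r in pair_rows})
            )
            report.similarity_context[leaf] = sim.mean
    return report, tree
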