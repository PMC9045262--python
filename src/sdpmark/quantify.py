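"""Marker-gene amplicon sequencing (MGAS) quantification of SDP composition.

Barcoded amplicon reads are demultiplexed by their inline 6-bp barcodes,
dereplicated into exact sequence features, classified against reference
amplicons at a 97% identity threshold with a consensus rule, and summarized
as per-sample SDP read counts and relative abundances:

    RA_SDP = NR_SDP / NR_assigned × 100

where NR_SDP is the number of reads assigned to the focal SDP and
NR_assigned the reads assigned to any SDP of the focal phylotype.  Low-depth
features (< 100 reads in a sample by default) are zeroed before
interpretation.  Detection limits are estimated by rarefaction, repeatability
by the intraclass correlation ICC(C,1), and community structure by Shannon
diversity, Bray-Curtis dissimilarity and PCoA.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .refdb import GeneRecord, SampleSheet, revcomp

logger = logging.getLogger("sdpmark")

UNASSIGNED = "UNASSIGNED"
DEFAULT_MIN_IDENTITY = 0.97
DEFAULT_TOP_WINDOW = 0.005
DEFAULT_MIN_COUNT = 100
BARCODE_LEN = 6


@dataclass
class ReadBatch:
    """Reads from one run or one sample: (read_id, sequence[, quality])."""

    reads: list[tuple]
    provenance: str = ""

    def __post_init__(self) -> None:
        for r in self.reads:
            if not r[1]:
                raise ValueError(f"empty sequence for read {r[0]!r}")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class FeatureTable:
    """Samples × unique-sequence counts, with each feature's representative."""

    counts: pd.DataFrame  # index: sample_id, columns: feature_id, integer
    sequences: dict[str, str]  # feature_id -> representative sequence

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative feature counts")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class SdpAbundanceTable:
    counts: pd.DataFrame  # samples × SDPs, reads (NR_SDP)
    relative: pd.DataFrame  # samples × SDPs, percent (RA_SDP); NaN when nothing assigned
    n_assigned: pd.Series
    n_unassigned: pd.Series
    empty_samples: list[str] = field(default_factory=list)


@dataclass
class RarefactionResult:
    depths: list[int]
    detection_prob: dict[tuple[str, int], float]  # (SDP, depth) -> fraction of reps
    reps: int
    seed: int
    with_replacement: bool = False


@dataclass
class IccResult:
    icc_c1: float
    ms_between: float
    ms_error: float
    n_subjects: int
    k_raters: int


# ---------------------------------------------------------------------------
# demultiplexing


def demultiplex(
    batch: ReadBatch, sheet: Sequence[SampleSheet]
) -> tuple[dict[str, ReadBatch], int]:
    """Assign reads to samples by exact match of the first 6 nt to a barcode.

    A hit on the forward barcode keeps the read as is; a hit on the reverse
    barcode means the read comes from the opposite strand and is
    reverse-complemented so every retained read is in amplicon orientation.
    Barcodes are trimmed.  Returns (sample_id -> batch, n_unassigned);
    assigned + unassigned always equals the input count.
    """
    lookup: dict[str, tuple[str, bool]] = {}
    for s in sheet:
        for bc, is_rev in ((s.barcode_fwd, False), (s.barcode_rev, True)):
            if bc in lookup:
                raise ValueError(
                    f"barcode {bc} collides between samples "
                    f"{lookup[bc][0]!r} and {s.sample_id!r}"
                )
            lookup[bc] = (s.sample_id, is_rev)

    out: dict[str, list[tuple]] = {s.sample_id: [] for s in sheet}
    unassigned = 0
    for read in batch.reads:
        rid, seq = read[0], read[1]
        hit = lookup.get(seq[:BARCODE_LEN])
        if hit is None:
            unassigned += 1
            continue
        sample_id, is_rev = hit
        payload = seq[BARCODE_LEN:]
        if not payload:
            unassigned += 1
            continue
        if is_rev:
            payload = revcomp(payload)
        out[sample_id].append((rid, payload))
    if unassigned:
        logger.info("demultiplex: %d/%d reads unassigned", unassigned, len(batch))
    return (
        {sid: ReadBatch(reads, provenance=batch.provenance) for sid, reads in out.items()},
        unassigned,
    )


# ---------------------------------------------------------------------------
# dereplication and classification


def dereplicate(batches: Mapping[str, ReadBatch] | ReadBatch) -> FeatureTable:
    """Collapse identical sequences into features; counts are multiplicities.

    Features are ordered by total abundance (descending), ties broken by
    sequence lexicographic order, and named F000001, F000002, ...
    """
    if isinstance(batches, ReadBatch):
        batches = {"sample": batches}
    per_sample: dict[str, Counter] = {
        sid: Counter(r[1] for r in b.reads) for sid, b in batches.items()
    }
    total: Counter = Counter()
    for c in per_sample.values():
        total.update(c)
    ordered = sorted(total, key=lambda s: (-total[s], s))
    fids = [f"F{i:06d}" for i in range(1, len(ordered) + 1)]
    seq2fid = dict(zip(ordered, fids))
    counts = pd.DataFrame(
        0, index=list(per_sample), columns=fids, dtype=int
    )
    for sid, c in per_sample.items():
        for seq, n in c.items():
            counts.at[sid, seq2fid[seq]] = n
    return FeatureTable(counts, {fid: seq for seq, fid in seq2fid.items()})


def percent_identity(a: str, b: str) -> float:
    """Global-alignment fractional identity, terminal gaps excluded.

    Identity = matched columns / alignment columns, after stripping indel
    runs at either end of the global (Needleman-Wunsch) alignment — the
    end-free dialect commonly reported as "blast identity" for near-full-
    length hits.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    ops = []  # (count, op) from extended cigar
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    cols = sum(n for n, _ in ops)
    if cols == 0:
        return 0.0
    eq = sum(n for n, op in ops if op == "=")
    return eq / cols


def classify(
    features: FeatureTable,
    references: Sequence[GeneRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    top_window: float = DEFAULT_TOP_WINDOW,
) -> dict[str, str]:
    """Assign each feature an SDP by consensus over its best reference hits.

    Every feature is globally aligned to every reference amplicon; hits below
    ``min_identity`` are discarded, and among hits within ``top_window`` of
    the best identity the SDP is assigned only if they all agree — otherwise
    the feature is UNASSIGNED.  Reference order never matters.
    """
    if not references:
        raise ValueError("empty reference amplicon set")
    refs = [(r.sdp if r.sdp else r.seq_id, r.sequence) for r in references]
    out: dict[str, str] = {}
    for fid in features.feature_ids:
        seq = features.sequences[fid]
        hits = [(percent_identity(seq, rseq), sdp) for sdp, rseq in refs]
        hits = [(pid, sdp) for pid, sdp in hits if pid >= min_identity]
        if not hits:
            out[fid] = UNASSIGNED
            continue
        best = max(pid for pid, _ in hits)
        top = {sdp for pid, sdp in hits if pid >= best - top_window}
        out[fid] = top.pop() if len(top) == 1 else UNASSIGNED
    return out


def abundance(
    features: FeatureTable, assignments: Mapping[str, str]
) -> SdpAbundanceTable:
    """Per-sample SDP read counts and RA_SDP = NR_SDP / NR_assigned × 100.

    Only assigned reads enter the denominator; the unassigned fraction is
    reported separately.  Samples with zero assigned reads get NaN relative
    abundances and are listed in ``empty_samples`` rather than propagating
    silently.
    """
    sdps = sorted({s for s in assignments.values() if s != UNASSIGNED})
    counts = pd.DataFrame(0, index=features.sample_ids, columns=sdps, dtype=int)
    unassigned = pd.Series(0, index=features.sample_ids, dtype=int)
    for fid in features.feature_ids:
        sdp = assignments.get(fid, UNASSIGNED)
        col = features.counts[fid]
        if sdp == UNASSIGNED:
            unassigned += col
        else:
            counts[sdp] += col
    n_assigned = counts.sum(axis=1)
    relative = counts.div(n_assigned, axis=0) * 100.0
    empty = sorted(n_assigned.index[n_assigned == 0])
    if empty:
        logger.warning("no assigned reads in samples: %s", empty)
    return SdpAbundanceTable(counts, relative, n_assigned, unassigned, empty)


def filter_low_abundance(
    table: FeatureTable, min_count: int = DEFAULT_MIN_COUNT
) -> FeatureTable:
    """Zero per-sample feature counts below ``min_count`` (strict <).

    The rule is per sample: a feature may survive in a deep sample and be
    zeroed in a shallow one.  Features left empty everywhere are dropped.
    """
    counts = table.counts.copy()
    counts[counts < min_count] = 0
    keep = counts.columns[counts.sum(axis=0) > 0]
    if min_count == 0:
        keep = counts.columns
    counts = counts[keep]
    return FeatureTable(counts, {f: table.sequences[f] for f in keep})


def cluster_otus(features: FeatureTable, identity: float = 0.97) -> FeatureTable:
    """Greedy de-novo centroid clustering of features into OTUs.

    Features are visited in abundance-descending order (ties lexicographic by
    sequence); each joins the first centroid it matches at >= ``identity``,
    else founds a new centroid.  Counts are summed into centroids.  The
    greedy result is order-defined, not globally optimal.
    """
    order = sorted(
        features.feature_ids,
        key=lambda f: (-int(features.counts[f].sum()), features.sequences[f]),
    )
    centroids: list[str] = []  # feature ids
    membership: dict[str, str] = {}
    for fid in order:
        seq = features.sequences[fid]
        for cid in centroids:
            if percent_identity(seq, features.sequences[cid]) >= identity:
                membership[fid] = cid
                break
        else:
            centroids.append(fid)
            membership[fid] = fid
    counts = pd.DataFrame(
        0, index=features.sample_ids, columns=centroids, dtype=int
    )
    for fid, cid in membership.items():
        counts[cid] += features.counts[fid]
    renamed = {cid: f"OTU{i:04d}" for i, cid in enumerate(centroids, 1)}
    counts.columns = [renamed[c] for c in centroids]
    seqs = {renamed[c]: features.sequences[c] for c in centroids}
    return FeatureTable(counts, seqs)


# ---------------------------------------------------------------------------
# rarefaction and repeatability


def rarefy_detection(
    sdp_counts: Mapping[str, int],
    depths: Sequence[int],
    reps: int = 100,
    seed: int = 0,
    detection_min_reads: int = 1,
    with_replacement: bool = False,
) -> RarefactionResult:
    """Detection probability of each SDP under random subsampling of reads.

    At each depth the sample's reads are subsampled ``reps`` times —
    without replacement by default (classical rarefaction; depth capped at
    the total), or with replacement (multinomial over the observed
    proportions, which admits closed-form checks).  An SDP is detected in a
    replicate when it receives at least ``detection_min_reads`` reads.
    """
    rng = np.random.default_rng(seed)
    sdps = sorted(sdp_counts)
    totals = np.array([sdp_counts[s] for s in sdps], dtype=np.int64)
    grand = int(totals.sum())
    if grand == 0:
        raise ValueError("no reads to rarefy")
    probs = totals / grand
    detection: dict[tuple[str, int], float] = {}
    for depth in depths:
        if with_replacement:
            draws = rng.multinomial(depth, probs, size=reps)
        else:
            d = min(depth, grand)
            draws = rng.multivariate_hypergeometric(totals, d, size=reps)
        det = (draws >= detection_min_reads).mean(axis=0)
        for s, p in zip(sdps, det):
            detection[(s, int(depth))] = float(p)
    return RarefactionResult(
        [int(d) for d in depths], detection, reps, seed, with_replacement
    )


def min_reads_for_detection(
    result: RarefactionResult, target_prob: float = 0.95
) -> dict[str, int | None]:
    """Smallest evaluated depth at which detection probability >= target.

    None when no evaluated depth reaches the target.  Monotone in
    ``target_prob`` by construction.
    """
    sdps = sorted({s for s, _ in result.detection_prob})
    out: dict[str, int | None] = {}
    for s in sdps:
        ok = [d for d in sorted(result.depths) if result.detection_prob[(s, d)] >= target_prob]
        out[s] = ok[0] if ok else None
    return out


def icc_c1(measurements: np.ndarray) -> IccResult:
    """Intraclass correlation ICC(C,1): two-way mixed model, consistency.

    ``measurements`` is subjects × raters (here: samples × replicate runs).
    ICC(C,1) = (MS_BS − MS_E) / (MS_BS + (k−1)·MS_E) with MS_BS the
    between-subject and MS_E the residual mean square of the two-way ANOVA
    without interaction.  A matrix with zero variance everywhere yields NaN
    (0/0) with a warning.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-D subjects × raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 subjects and 2 raters")
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_bs = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_bs + (k - 1) * ms_e
    if denom == 0:
        logger.warning("ICC undefined: zero variance in measurements")
        return IccResult(float("nan"), ms_bs, ms_e, n, k)
    return IccResult((ms_bs - ms_e) / denom, ms_bs, ms_e, n, k)


# ---------------------------------------------------------------------------
# diversity


def shannon_diversity(fractions: Sequence[float]) -> float:
    """Shannon diversity H' = −Σ p·ln p (natural log) over nonzero fractions."""
    p = np.asarray(fractions, dtype=float)
    if (p < 0).any():
        raise ValueError("negative fractions")
    total = p.sum()
    if total == 0:
        raise ValueError("all fractions zero")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between the rows of a samples × taxa table."""
    ids = list(table.index)
    x = table.to_numpy(dtype=float)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _braycurtis(x[i], x[j])
    return pd.DataFrame(out, index=ids, columns=ids)


def pcoa(dissim: pd.DataFrame, n_axes: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (PCoA) of a dissimilarity matrix.

    Returns the first ``n_axes`` coordinates per sample and the full
    eigenvalue spectrum.
    """
    dm = SkbioDistanceMatrix(dissim.to_numpy(), ids=[str(i) for i in dissim.index])
    res = _skbio_pcoa(dm, number_of_dimensions=min(n_axes, len(dissim) - 1))
    coords = res.samples.iloc[:, :n_axes]
    coords.index = list(dissim.index)
    return coords, res.eigvals.to_numpy()
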