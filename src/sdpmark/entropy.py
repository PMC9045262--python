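"""Shannon-entropy marker screening.

Candidate single-copy marker genes are screened on per-site Shannon entropy of
their cross-genome alignment: a usable marker carries a hypervariable core
(enough divergence to tell SDPs apart) flanked by conserved runs long enough
to host primers, with the resulting amplicon in a sequencer-friendly length
range (150–550 bp by default) and primers specific to the focal phylotype.

Entropy is reported in bits.  Gaps may be counted as a fifth character
(``include_gap``, the oligotyping convention and the default) or ignored with
renormalization over A/C/G/T (``ignore_gap``); N is never counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .delineate import SdpPartition
from .refdb import GeneRecord, MultipleAlignment, revcomp

logger = logging.getLogger("sdpmark")

GapMode = Literal["include_gap", "ignore_gap"]

DEFAULT_WINDOW = 20
DEFAULT_STEP = 5
DEFAULT_CONSERVED_MAX_SITE_ENTROPY = 0.2  # bits/site
DEFAULT_MIN_CONSERVED_LEN = 17  # columns; the shortest published primer length
DEFAULT_LEN_BOUNDS = (150, 550)  # bp, ungapped

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class EntropyProfile:
    gene_name: str
    per_site: np.ndarray  # bits, length = alignment length
    gap_mode: GapMode
    n_rows: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_site))


@dataclass
class WindowProfile:
    window: int
    step: int
    window_means: np.ndarray
    window_starts: np.ndarray  # 0-based; window k covers [start, start+window)


@dataclass
class RegionCall:
    start: int  # 0-based, half-open on alignment columns
    end: int
    klass: Literal["conserved", "hypervariable"]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PrimerPair:
    """A primer pair, both given 5'→3'; rev anneals to the reverse complement."""

    name: str
    fwd: str
    rev: str

    def __post_init__(self) -> None:
        self.fwd = self.fwd.upper().replace("U", "T")
        self.rev = self.rev.upper().replace("U", "T")
        for p in (self.fwd, self.rev):
            if not p or set(p) - set(IUPAC):
                raise ValueError(f"primer pair {self.name!r}: invalid primer {p!r}")


@dataclass
class AmpliconCandidate:
    gene_name: str
    fwd_site: tuple[int, int]  # conserved interval hosting the forward primer
    rev_site: tuple[int, int]
    amplicon_interval: tuple[int, int]  # alignment columns, primer sites included
    length_bp: int  # ungapped, measured on the reference (first) row
    min_inter_sdp_divergence: float  # percent
    specific: bool = True


# Published marker primers for the A. cerana Gilliamella assay (both 5'→3').
FRR_PRIMERS = PrimerPair("frr", "GCTGAAGATGCAAGAAC", "GCATCACGACGAATATT")
NUSA_PRIMERS = PrimerPair("nusA", "CTTGAAATTGAAGAACT", "GTACCTTGTTCAGCTAA")
PTH_PRIMERS = PrimerPair("pth", "AAACTTATTGTAGG", "CCACTTAAATTCATAAA")


def site_entropy(aln: MultipleAlignment, gap_mode: GapMode = "include_gap") -> EntropyProfile:
    """Per-column Shannon entropy H = −Σ p·log2 p over observed symbols.

    ``include_gap`` counts '-' as a fifth symbol; ``ignore_gap`` renormalizes
    over A/C/G/T.  N is never counted.  A column with no countable symbol
    gets H = 0 with a warning.
    """
    if aln.n_rows < 2:
        raise ValueError("entropy needs an alignment with at least 2 rows")
    if gap_mode not in ("include_gap", "ignore_gap"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    symbols = "ACGT-" if gap_mode == "include_gap" else "ACGT"
    H = np.zeros(aln.length)
    warned = False
    for i in range(aln.length):
        col = aln.column(i)
        counts = np.array([col.count(s) for s in symbols], dtype=float)
        total = counts.sum()
        if total == 0:
            if not warned:
                logger.warning(
                    "alignment %s: column %d has no countable symbols; H set to 0",
                    aln.gene_name, i,
                )
                warned = True
            continue
        p = counts[counts > 0] / total
        H[i] = max(0.0, float(-(p * np.log2(p)).sum()))
    return EntropyProfile(aln.gene_name, H, gap_mode, n_rows=aln.n_rows)


def average_entropy(
    aln: MultipleAlignment,
    subset_rows: Sequence[str] | None = None,
    gap_mode: GapMode = "include_gap",
) -> float:
    """Average Shannon entropy (ASE): mean per-site entropy over the gene.

    With ``subset_rows`` the entropy is recomputed on that row subset, so the
    same gene can be summarized at phylotype level (all strains) or per SDP.
    """
    if subset_rows is not None:
        aln = aln.subset_rows(subset_rows)
    return site_entropy(aln, gap_mode).mean


def window_entropy(
    profile: EntropyProfile, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> WindowProfile:
    """Sliding-window means of per-site entropy (20-bp window, 5-bp step).

    Trailing columns not covered by a full window are dropped.
    """
    L = len(profile.per_site)
    if L < window:
        raise ValueError(f"alignment length {L} shorter than window {window}")
    n_win = (L - window) // step + 1
    starts = np.arange(n_win) * step
    means = np.array(
        [profile.per_site[s : s + window].mean() for s in starts]
    )
    return WindowProfile(window, step, means, starts)


def call_regions(
    wp: WindowProfile,
    profile: EntropyProfile,
    conserved_max_site_entropy: float = DEFAULT_CONSERVED_MAX_SITE_ENTROPY,
    min_conserved_len: int = DEFAULT_MIN_CONSERVED_LEN,
    hyper_min_mean: float | None = None,
) -> list[RegionCall]:
    """Call conserved (primer-ready) and hypervariable regions on a gene.

    Conserved: maximal runs of columns with per-site entropy at or below
    ``conserved_max_site_entropy`` and run length >= ``min_conserved_len``.
    Hypervariable: the union of sliding windows whose mean entropy exceeds
    ``hyper_min_mean`` (the gene-wide mean by default).  Overlaps are resolved
    in favour of conserved.  Empty call lists are valid: a uniformly variable
    gene has no conserved calls, a flat gene no hypervariable ones.
    """
    if hyper_min_mean is None:
        hyper_min_mean = profile.mean
    H = profile.per_site
    calls: list[RegionCall] = []

    conserved: list[tuple[int, int]] = []
    i = 0
    L = len(H)
    while i < L:
        if H[i] <= conserved_max_site_entropy:
            j = i
            while j < L and H[j] <= conserved_max_site_entropy:
                j += 1
            if j - i >= min_conserved_len:
                conserved.append((i, j))
            i = j
        else:
            i += 1

    hot = [
        (int(s), int(s) + wp.window)
        for s, m in zip(wp.window_starts, wp.window_means)
        if m > hyper_min_mean
    ]
    hyper = _merge_intervals(hot)
    hyper = _subtract_intervals(hyper, conserved)

    calls.extend(RegionCall(s, e, "conserved") for s, e in conserved)
    calls.extend(RegionCall(s, e, "hypervariable") for s, e in hyper)
    calls.sort(key=lambda c: c.start)
    return calls


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract_intervals(
    ivals: list[tuple[int, int]], minus: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s, e in ivals:
        pieces = [(s, e)]
        for ms, me in minus:
            nxt = []
            for ps, pe in pieces:
                if me <= ps or ms >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < ms:
                    nxt.append((ps, ms))
                if me < pe:
                    nxt.append((me, pe))
            pieces = nxt
        out.extend(p for p in pieces if p[1] > p[0])
    return _merge_intervals(out)


def _ungapped_length(aln: MultipleAlignment, start: int, end: int) -> int:
    ref = aln.rows[0][start:end]
    return len(ref) - ref.count("-")


def enumerate_amplicons(
    regions: list[RegionCall],
    aln: MultipleAlignment,
    partition: SdpPartition,
    len_bounds: tuple[int, int] = DEFAULT_LEN_BOUNDS,
) -> list[AmpliconCandidate]:
    """Enumerate candidate amplicons: conserved flanks around a hypervariable core.

    Every ordered pair of conserved regions enclosing at least one
    hypervariable call, with ungapped span length (measured on the first
    alignment row, primer sites included) inside ``len_bounds``, becomes a
    candidate.  Each is annotated with the minimum pairwise inter-SDP
    divergence of the enclosed region and the list is sorted by that
    divergence, highest first.
    """
    conserved = [r for r in regions if r.klass == "conserved"]
    hyper = [r for r in regions if r.klass == "hypervariable"]
    out: list[AmpliconCandidate] = []
    for a, b in combinations(sorted(conserved, key=lambda r: r.start), 2):
        cores = [h for h in hyper if a.end <= h.start and h.end <= b.start]
        if not cores:
            continue
        length = _ungapped_length(aln, a.start, b.end)
        if not len_bounds[0] <= length <= len_bounds[1]:
            continue
        core_start = min(h.start for h in cores)
        core_end = max(h.end for h in cores)
        sim = inter_sdp_similarity(aln.slice_columns(core_start, core_end), partition)
        divergence = 100.0 - sim.mean if sim.n_pairs else 0.0
        out.append(
            AmpliconCandidate(
                gene_name=aln.gene_name,
                fwd_site=(a.start, a.end),
                rev_site=(b.start, b.end),
                amplicon_interval=(a.start, b.end),
                length_bp=length,
                min_inter_sdp_divergence=divergence,
            )
        )
    out.sort(key=lambda c: -c.min_inter_sdp_divergence)
    return out


def _iupac_match(primer: str, window: str, three_prime_at_end: bool, max_mismatch: int,
                 require_3prime_exact: int) -> bool:
    mism = 0
    n = len(primer)
    for k in range(n):
        ok = window[k] in IUPAC[primer[k]]
        if not ok:
            # 3' terminal bases must match exactly
            pos_from_3prime = (n - 1 - k) if three_prime_at_end else k
            if pos_from_3prime < require_3prime_exact:
                return False
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def in_silico_pcr(
    primers: PrimerPair,
    templates: Sequence[GeneRecord],
    max_mismatch: int = 2,
    require_3prime_exact: int = 3,
) -> list[tuple[str, tuple[int, int], int]]:
    """Predict PCR products: Hamming primer matching with an exact 3' anchor.

    The forward primer is matched on the template strand; the reverse primer
    via its reverse complement (whose leftmost bases correspond to the
    primer's 3' end).  No indels are modelled.  Every (fwd, rev) site pair in
    the productive orientation is reported as (seq_id, [start, end), length);
    an empty list signals non-amplification.
    """
    rc_rev = revcomp(primers.rev)
    products = []
    for rec in templates:
        seq = rec.sequence
        fwd_hits = [
            i
            for i in range(len(seq) - len(primers.fwd) + 1)
            if _iupac_match(primers.fwd, seq[i : i + len(primers.fwd)], True,
                            max_mismatch, require_3prime_exact)
        ]
        # reverse site on the template: reverse-complement of the rev primer,
        # 3' anchor at the left end of the site
        rev_hits = [
            i
            for i in range(len(seq) - len(rc_rev) + 1)
            if _iupac_match(rc_rev[::-1], seq[i : i + len(rc_rev)][::-1], True,
                            max_mismatch, require_3prime_exact)
        ]
        for f in fwd_hits:
            for r in rev_hits:
                end = r + len(rc_rev)
                if f + len(primers.fwd) <= r:
                    products.append((rec.seq_id, (f, end), end - f))
    return products


@dataclass
class SimilaritySummary:
    mean: float  # percent
    sd: float
    n_pairs: int


def inter_sdp_similarity(
    aln_slice: MultipleAlignment, partition: SdpPartition
) -> SimilaritySummary:
    """Mean ± SD percent identity over all cross-SDP sequence pairs of a region.

    Identity is computed over columns where both rows are non-gap (positions
    with N excluded as uninformative).  Rows absent from the partition are
    ignored.
    """
    pairs = []
    rows = [
        (rid, row)
        for rid, row in zip(aln_slice.row_ids, aln_slice.rows)
        if rid in partition.labels
    ]
    for (id_a, a), (id_b, b) in combinations(rows, 2):
        if partition.labels[id_a] == partition.labels[id_b]:
            continue
        same = comp = 0
        for x, y in zip(a, b):
            if x in "-N" or y in "-N":
                continue
            comp += 1
            if x == y:
                same += 1
        if comp:
            pairs.append(100.0 * same / comp)
    if not pairs:
        return SimilaritySummary(float("nan"), float("nan"), 0)
    arr = np.array(pairs)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return SimilaritySummary(float(arr.mean()), sd, len(arr))


def screen_gene(
    aln: MultipleAlignment,
    partition: SdpPartition,
    gap_mode: GapMode = "include_gap",
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    conserved_max_site_entropy: float = DEFAULT_CONSERVED_MAX_SITE_ENTROPY,
    min_conserved_len: int = DEFAULT_MIN_CONSERVED_LEN,
    len_bounds: tuple[int, int] = DEFAULT_LEN_BOUNDS,
) -> tuple[EntropyProfile, WindowProfile, list[RegionCall], list[AmpliconCandidate]]:
    """Full screening pipeline for one gene alignment.

    Returns the entropy profile, its windowed summary, the region calls and
    the accepted amplicon candidates (possibly empty — a gene with no
    conserved flanks or no hypervariable core is thereby rejected).
    """
    profile = site_entropy(aln, gap_mode)
    wp = window_entropy(profile, window, step)
    regions = call_regions(
        wp, profile, conserved_max_site_entropy, min_conserved_len
    )
    candidates = enumerate_amplicons(regions, aln, partition, len_bounds)
    return profile, wp, regions, candidates
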