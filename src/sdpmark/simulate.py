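"""Synthetic SDP communities: gene families, ANI matrices, and mock amplicon reads.

The generator emulates the structure the screening and quantification stages
rely on: gene families evolved on a tree with long inter-SDP and short
intra-SDP branches and invariant primer flanks, ANI matrices with a clean
gap between intra- (≥ 96%) and inter-SDP (≤ 92%) identity, and barcoded mock
read sets drawn multinomially from known SDP proportions — mirroring mock
communities of 2–5 representative strains mixed at proportions from 0.02% to
50%.

Substitution model: per branch of length d (substitutions/site), each
variable site receives Poisson(d) hits, each replacing the base with one of
the 3 alternatives uniformly (Jukes-Cantor).  Expected identity between
sequences separated by total path length t is 1/4 + 3/4·exp(−4t/3) on
variable sites.  The model is a fixture generator, not a biological claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .delineate import SdpPartition
from .refdb import MultipleAlignment, SampleSheet, revcomp, tree_from_newick

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimSpec:
    """Parameters of a simulated SDP-structured gene family and mock run."""

    n_sdps: int = 5
    strains_per_sdp: int = 3
    # divergences are expected substitutions/site SEPARATING two lineages
    # (split half-and-half over the two branches of their path)
    inter_sdp_divergence: float = 0.09  # ~91% cross-SDP identity
    intra_sdp_divergence: float = 0.01  # within the <5% intra-SDP bound
    gene_length: int = 240
    conserved_flank_len: int = 17
    error_rate: float = 0.0  # per-base read error
    proportions: dict[str, float] | None = None  # SDP -> fraction
    depth: int = 10000  # reads per sample
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.inter_sdp_divergence, self.intra_sdp_divergence):
            if not 0 <= d < 0.75:
                raise ValueError("divergence must be in [0, 0.75)")
        if self.proportions is not None:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"proportions sum to {total}, not 1")
        if 2 * self.conserved_flank_len >= self.gene_length:
            raise ValueError("flanks longer than the gene")


def _mutate(seq: np.ndarray, variable: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of length d: Poisson(d) substitutions per variable site."""
    out = seq.copy()
    if d <= 0:
        return out
    hits = rng.poisson(d, size=variable.sum())
    idx = np.flatnonzero(variable)
    for pos, k in zip(idx, hits):
        for _ in range(int(k)):
            cur = out[pos]
            alt = _BASES[_BASES != cur]
            out[pos] = alt[rng.integers(3)]
    return out


def simulate_gene_family(
    spec: SimSpec,
) -> tuple[MultipleAlignment, SdpPartition, TreeNode]:
    """Evolve a gene family on a balanced SDP tree.

    Root → one ancestor per SDP (branch: inter_sdp_divergence / 2) → strain
    leaves (branch: intra_sdp_divergence / 2), so two leaves from different
    SDPs are separated by inter + intra substitutions/site in expectation and
    two strains of one SDP by intra.  Columns in the two conserved flanks are
    held invariant so the entropy screen can find primer sites; set
    conserved_flank_len = 0 to disable them.  Deterministic for a fixed seed.
    Genome ids are "<SDP>.s<j>"; the returned partition maps them to
    SDP_1..SDP_k.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.gene_length
    variable = np.ones(L, dtype=bool)
    if spec.conserved_flank_len:
        variable[: spec.conserved_flank_len] = False
        variable[L - spec.conserved_flank_len :] = False
    root = _BASES[rng.integers(4, size=L)]

    b_inter = spec.inter_sdp_divergence / 2
    b_intra = spec.intra_sdp_divergence / 2
    row_ids, rows, labels = [], [], {}
    clades = []
    for i in range(1, spec.n_sdps + 1):
        sdp = f"SDP_{i}"
        anc = _mutate(root, variable, b_inter, rng)
        leaves = []
        for j in range(1, spec.strains_per_sdp + 1):
            gid = f"{sdp}.s{j}"
            leaf = _mutate(anc, variable, b_intra, rng)
            row_ids.append(gid)
            rows.append(leaf.tobytes().decode())
            labels[gid] = sdp
            leaves.append(f"{gid}:{b_intra}")
        clades.append(f"({','.join(leaves)}):{b_inter}")
    tree = tree_from_newick(f"({','.join(clades)});")
    aln = MultipleAlignment("simulated", row_ids, rows)
    return aln, SdpPartition(labels), tree


def simulate_ani(
    partition: SdpPartition,
    seed: int = 0,
    intra_range: tuple[float, float] = (96.0, 99.5),
    inter_range: tuple[float, float] = (77.0, 83.0),
) -> "AniMatrix":
    """Draw a symmetric ANI matrix consistent with a given partition.

    Intra-SDP values are uniform in ``intra_range`` (≥ 96 by default),
    inter-SDP values uniform in ``inter_range`` (centred near 80, echoing the
    typical inter-SDP regime, and well below the 95% rule).
    """
    from .refdb import AniMatrix

    rng = np.random.default_rng(seed)
    ids = sorted(partition.labels)
    n = len(ids)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            same = partition.labels[ids[i]] == partition.labels[ids[j]]
            lo, hi = intra_range if same else inter_range
            vals[i, j] = vals[j, i] = rng.uniform(lo, hi)
    return AniMatrix(ids, vals)


def default_mock_design(sdps: list[str]) -> dict[str, dict[str, float]]:
    """24 mock community compositions over (up to) five SDPs.

    Mirrors the published design: one community with all five members at
    equal proportion, five leave-one-out communities of four, a set of
    three-member communities, and a graded series spanning 0.02%–50%.
    """
    if len(sdps) < 2:
        raise ValueError("mock design needs at least 2 SDPs")
    s = list(sdps)
    k = len(s)
    designs: list[dict[str, float]] = []
    designs.append({x: 1.0 / k for x in s})  # equal, all members
    for drop in s:  # leave-one-out
        rest = [x for x in s if x != drop]
        designs.append({x: 1.0 / len(rest) for x in rest})
    for i in range(k):  # three-member communities
        trio = [s[i % k], s[(i + 1) % k], s[(i + 2) % k]]
        designs.append({x: 1.0 / 3 for x in sorted(set(trio))})
    # graded series down to 0.02% of the first member
    for low in (0.5, 0.2, 0.05, 0.01, 0.002, 0.0002):
        rest = [x for x in s if x != s[0]]
        comp = {s[0]: low}
        for x in rest:
            comp[x] = (1.0 - low) / len(rest)
        designs.append(comp)
    i = 0
    while len(designs) < 24:  # pairwise skewed mixtures to fill the panel
        a, b = s[i % k], s[(i + 1) % k]
        frac = [0.25, 0.1, 0.02][i % 3]
        designs.append({a: frac, b: 1.0 - frac})
        i += 1
    return {f"M{i:02d}": d for i, d in enumerate(designs[:24], 1)}


_BARCODE_ALPHABET = "ACGT"


def make_sample_sheet(
    compositions: dict[str, dict[str, float]], marker: str = "sim", seed: int = 0
) -> list[SampleSheet]:
    """Assign distinct random 6-bp forward/reverse barcodes to each mock sample."""
    rng = np.random.default_rng(seed)
    used: set[str] = set()

    def fresh() -> str:
        while True:
            bc = "".join(_BARCODE_ALPHABET[i] for i in rng.integers(4, size=6))
            if bc not in used:
                used.add(bc)
                return bc

    return [
        SampleSheet(sid, fresh(), fresh(), marker=marker, known_composition=comp)
        for sid, comp in compositions.items()
    ]


def _seq_with_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for pos in hit:
        alt = _BASES[_BASES != arr[pos]]
        arr[pos] = alt[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_mock_reads(
    amplicons: dict[str, str],
    sheet: list[SampleSheet],
    depth: int = 10000,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple["ReadBatch", list[tuple[str, str, str]]]:
    """Barcoded mock amplicon reads from known SDP proportions.

    ``amplicons`` maps SDP → representative amplicon sequence.  Per sample,
    ``depth`` reads are drawn multinomially from its known composition; each
    read gets per-base substitution errors at ``error_rate``, a random
    orientation, and the sample's 6-bp barcode prepended (forward barcode +
    amplicon, or reverse barcode + reverse-complemented amplicon).  Returns
    the pooled batch plus a truth log of (read_id, sample_id, sdp).

    Error-free reads of one (sdp, orientation) class share a single string
    object, so deep mock panels stay cheap to hold in memory.
    """
    from .quantify import ReadBatch

    rng = np.random.default_rng(seed)
    reads: list[tuple] = []
    truth: list[tuple[str, str, str]] = []
    serial = 0
    for s in sheet:
        if not s.known_composition:
            raise ValueError(f"sample {s.sample_id!r} has no known composition")
        sdps = sorted(s.known_composition)
        missing = [x for x in sdps if x not in amplicons]
        if missing:
            raise KeyError(f"no amplicon for SDPs {missing}")
        probs = np.array([s.known_composition[x] for x in sdps])
        counts = rng.multinomial(depth, probs / probs.sum())
        for sdp, n in zip(sdps, counts):
            template = amplicons[sdp]
            n_rev = int(rng.binomial(n, 0.5))
            plans = [(n - n_rev, False), (n_rev, True)]
            for m, is_rev in plans:
                if m == 0:
                    continue
                if error_rate <= 0:
                    body = (
                        s.barcode_rev + revcomp(template)
                        if is_rev
                        else s.barcode_fwd + template
                    )
                    for _ in range(m):
                        serial += 1
                        rid = f"read{serial:08d}"
                        reads.append((rid, body))
                        truth.append((rid, s.sample_id, sdp))
                else:
                    for _ in range(m):
                        serial += 1
                        rid = f"read{serial:08d}"
                        seq = _seq_with_errors(template, error_rate, rng)
                        body = (
                            s.barcode_rev + revcomp(seq)
                            if is_rev
                            else s.barcode_fwd + seq
                        )
                        reads.append((rid, body))
                        truth.append((rid, s.sample_id, sdp))
    return ReadBatch(reads, provenance="simulated"), truth


def representative_amplicons(
    aln: MultipleAlignment, partition: SdpPartition
) -> dict[str, str]:
    """One ungapped representative sequence per SDP (its first member row)."""
    out: dict[str, str] = {}
    for sdp in partition.sdps:
        members = [r for r in aln.row_ids if partition.labels.get(r) == sdp]
        if members:
            row = aln.rows[aln.row_ids.index(members[0])]
            out[sdp] = row.replace("-", "")
    return out
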