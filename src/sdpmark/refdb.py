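"""Reference-database I/O: gene FASTA, alignments, ANI matrices, sample sheets, trees.

The in-memory reference database binds marker-gene sequences to the genomes,
phylotypes and sequence-discrete populations (SDPs) they come from.  FASTA
headers may carry that binding inline as ``seq_id|genome_id|phylotype|gene``;
plain headers fall back to seq_id-only records.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

logger = logging.getLogger("sdpmark")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneRecord:
    """One gene sequence tied to its genome, phylotype and (optionally) SDP."""

    seq_id: str
    sequence: str
    genome_id: str = ""
    phylotype: str = ""
    gene_name: str = ""
    sdp: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.seq_id!r}")
        # uppercase on ingest; RNA U mapped to T
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - set("ACGTN-")
        if bad:
            raise ValueError(
                f"record {self.seq_id!r} contains non-nucleotide characters {sorted(bad)}"
            )


@dataclass
class MultipleAlignment:
    """A gapped nucleotide alignment with one row per sequence."""

    gene_name: str
    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows differ in length")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids in alignment")
        if not self.rows:
            raise ValueError("empty alignment")
        lens = {len(r) for r in self.rows}
        if len(lens) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lens)}")
        if self.length < 1:
            raise ValueError("alignment must have at least one column")
        self.rows = [r.upper().replace("U", "T") for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)

    def slice_columns(self, start: int, end: int) -> "MultipleAlignment":
        """Sub-alignment over columns [start, end), 0-based half-open."""
        if not (0 <= start <= end <= self.length):
            raise ValueError(f"column slice [{start}, {end}) outside alignment")
        return MultipleAlignment(
            self.gene_name, list(self.row_ids), [r[start:end] for r in self.rows]
        )

    def subset_rows(self, ids: Sequence[str]) -> "MultipleAlignment":
        idx = {rid: i for i, rid in enumerate(self.row_ids)}
        missing = [r for r in ids if r not in idx]
        if missing:
            raise KeyError(f"rows not in alignment: {missing}")
        return MultipleAlignment(
            self.gene_name, list(ids), [self.rows[idx[r]] for r in ids]
        )


@dataclass
class AniMatrix:
    """Symmetric pairwise genome ANI, percent in [0, 100], diagonal 100."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate genome ids in ANI matrix")
        if self.values.shape != (n, n):
            raise ValueError(
                f"ANI matrix shape {self.values.shape} does not match {n} ids"
            )
        if n == 0:
            raise ValueError("empty ANI matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("ANI matrix not symmetric")
        if (self.values < 0).any() or (self.values > 100).any():
            raise ValueError("ANI values outside [0, 100]")

    def pair(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


@dataclass
class SampleSheet:
    """One amplicon library: inline 6-bp barcodes and optional known composition."""

    sample_id: str
    barcode_fwd: str
    barcode_rev: str
    marker: str = ""
    known_composition: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.barcode_fwd = self.barcode_fwd.upper()
        self.barcode_rev = self.barcode_rev.upper()
        for bc in (self.barcode_fwd, self.barcode_rev):
            if len(bc) != 6 or set(bc) - set("ACGT"):
                raise ValueError(
                    f"sample {self.sample_id!r}: barcodes must be exactly 6 nt of ACGT, got {bc!r}"
                )
        if self.known_composition is not None:
            total = sum(self.known_composition.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"sample {self.sample_id!r}: composition sums to {total}, not 1"
                )


def _parse_header(header: str) -> dict[str, str]:
    parts = header.split("|")
    if len(parts) == 4:
        return {
            "seq_id": parts[0],
            "genome_id": parts[1],
            "phylotype": parts[2],
            "gene_name": parts[3],
        }
    return {"seq_id": header, "genome_id": "", "phylotype": "", "gene_name": ""}


def read_fasta(path: str | Path) -> list[GeneRecord]:
    """Read gene records from FASTA; headers parsed as seq_id|genome|phylotype|gene."""
    path = Path(path)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = _parse_header(rec.description.strip())
        if meta["seq_id"] in seen:
            raise ValueError(f"duplicate seq_id {meta['seq_id']!r} in {path}")
        seen.add(meta["seq_id"])
        records.append(GeneRecord(sequence=str(rec.seq), **meta))
    if not records:
        logger.warning("no FASTA entries in %s", path)
    return records


def write_fasta(records: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.genome_id or r.phylotype or r.gene_name:
                header = f"{r.seq_id}|{r.genome_id}|{r.phylotype}|{r.gene_name}"
            else:
                header = r.seq_id
            fh.write(f">{header}\n{r.sequence}\n")


def read_alignment(path: str | Path, gene_name: str = "") -> MultipleAlignment:
    """Read a FASTA alignment (all rows equal length)."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"empty alignment file {path}")
    ids = [r.description.strip().split("|")[0] for r in recs]
    return MultipleAlignment(gene_name or Path(path).stem, ids, [str(r.seq) for r in recs])


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.row_ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


def read_ani_matrix(path: str | Path) -> AniMatrix:
    """Read a TSV ANI table; fractions rescaled ×100, symmetrized by the mean.

    ANIb is directional, so (i, j) and (j, i) may differ on disk; the single
    pairwise gANI value used for delineation is their arithmetic mean.  The
    diagonal is forced to 100.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"ANI table is not square: {df.shape[0]}×{df.shape[1]}")
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise ValueError("ANI table row and column ids differ")
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("ANI table contains missing values")
    off = vals[~np.eye(len(ids), dtype=bool)] if len(ids) > 1 else vals.ravel()
    if off.size and off.max() <= 1.0:
        vals = vals * 100.0
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 100.0)
    if (vals < 0).any() or (vals > 100).any():
        raise ValueError("ANI values outside [0, 100] after rescaling")
    return AniMatrix(ids, vals)


def write_ani_matrix(ani: AniMatrix, path: str | Path) -> None:
    pd.DataFrame(ani.values, index=ani.ids, columns=ani.ids).to_csv(
        path, sep="\t", float_format="%.6f"
    )


def read_newick(path: str | Path) -> TreeNode:
    """Read a Newick tree; duplicate leaf labels are rejected."""
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf labels in tree: {dupes}")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def newick_str(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tree_from_newick(s: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(s), format="newick", convert_underscores=False)
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def read_sample_sheet(path: str | Path) -> list[SampleSheet]:
    """Read a TSV sample sheet: sample_id, barcode_fwd, barcode_rev, marker[, composition].

    ``composition`` is optional and holds ``SDP:fraction`` pairs separated by
    commas, e.g. ``SDP_1:0.5,SDP_2:0.5``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "barcode_fwd", "barcode_rev"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheets = []
    for _, row in df.iterrows():
        comp = None
        if "composition" in df.columns and isinstance(row.get("composition"), str):
            comp = {}
            for part in row["composition"].split(","):
                sdp, frac = part.split(":")
                comp[sdp.strip()] = float(frac)
        sheets.append(
            SampleSheet(
                sample_id=row["sample_id"],
                barcode_fwd=row["barcode_fwd"],
                barcode_rev=row["barcode_rev"],
                marker=row.get("marker", "") or "",
                known_composition=comp,
            )
        )
    if len({s.sample_id for s in sheets}) != len(sheets):
        raise ValueError("duplicate sample ids in sheet")
    return sheets


def write_sample_sheet(sheets: Sequence[SampleSheet], path: str | Path) -> None:
    rows = []
    for s in sheets:
        comp = (
            ",".join(f"{k}:{v!r}" for k, v in s.known_composition.items())
            if s.known_composition
            else ""
        )
        rows.append(
            {
                "sample_id": s.sample_id,
                "barcode_fwd": s.barcode_fwd,
                "barcode_rev": s.barcode_rev,
                "marker": s.marker,
                "composition": comp,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
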