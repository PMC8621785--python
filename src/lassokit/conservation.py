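"""Bridge conservation from a precomputed multiple sequence alignment.

The conservation of a disulfide bridge is scored by how often each of its
two cysteines appears at the corresponding alignment columns: a bridge is
*highly* conserved when both columns carry a cysteine in more than 80% of
the aligned sequences, *poorly* conserved when either falls below 30%,
and *medium* otherwise.  Both boundaries are strict inequalities, so a
fraction of exactly 0.8 is medium, not high.

Alignments are consumed as FASTA or Clustal files (this module never
computes an alignment); near-duplicate rows (>= 95% pairwise identity by
default) can be removed greedily first.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MSA",
    "read_msa",
    "dedupe",
    "pairwise_identity",
    "cysteine_conservation",
    "bridge_class",
    "write_conservation_table",
]


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]  # aligned sequences, gap character '-'

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows must have equal length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)


def read_msa(path, format: str | None = None) -> MSA:
    """Read a FASTA or Clustal alignment via Bio.AlignIO."""
    from Bio import AlignIO

    if format is None:
        suffix = str(path).lower().rsplit(".", 1)[-1]
        format = "clustal" if suffix in ("aln", "clustal", "clw") else "fasta"
    aln = AlignIO.read(str(path), format)
    return MSA([rec.id for rec in aln], [str(rec.seq) for rec in aln])


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching residues over columns aligned in both rows."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


def dedupe(msa: MSA, identity: float = 0.95) -> MSA:
    """Greedily drop rows at or above ``identity`` to an already-kept row."""
    kept_ids: list[str] = []
    kept_rows: list[str] = []
    for rid, row in zip(msa.ids, msa.rows):
        if any(pairwise_identity(row, k) >= identity for k in kept_rows):
            continue
        kept_ids.append(rid)
        kept_rows.append(row)
    return MSA(kept_ids, kept_rows)


def cysteine_conservation(msa: MSA, col_i: int, col_j: int) -> tuple[float, float]:
    """Fraction of rows with a cysteine at each bridge column (1-based).

    Gap characters count as non-cysteine; the denominator is all aligned
    sequences.
    """
    for col in (col_i, col_j):
        if not 1 <= col <= msa.width:
            raise IndexError(f"column {col} outside alignment width {msa.width}")
    frac_i = sum(r[col_i - 1] == "C" for r in msa.rows) / len(msa)
    frac_j = sum(r[col_j - 1] == "C" for r in msa.rows) / len(msa)
    return frac_i, frac_j


def bridge_class(frac_i: float, frac_j: float) -> str:
    """Classify bridge conservation: high (> 0.80 both), poor (< 0.30 either),
    else medium."""
    for f in (frac_i, frac_j):
        if not 0.0 <= f <= 1.0:
            raise ValueError("conservation fractions must lie in [0, 1]")
    if frac_i < 0.30 or frac_j < 0.30:
        return "poor"
    if frac_i > 0.80 and frac_j > 0.80:
        return "high"
    return "medium"


def write_conservation_table(path, records) -> None:
    """TSV of (id, col_i, col_j, frac_i, frac_j, class) records."""
    import pandas as pd

    pd.DataFrame(
        records,
        columns=["id", "col_i", "col_j", "frac_i", "frac_j", "class"],
    ).to_csv(path, sep="\t", index=False)
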