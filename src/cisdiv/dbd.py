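"""Lineage-exclusive substitution screen over aligned TF orthologues.

Given a multiple protein alignment of a DNA-binding domain across
species, report the alignment columns where the focal taxon carries a
residue different from an otherwise invariant residue shared by every
other taxon — the decision kernel used to flag candidate TFs for
lineage-specific adaptive change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GAPS = set("-.")


@dataclass
class ProteinAlignment:
    taxa: list
    rows: list
    focal_taxon: str = None

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if self.focal_taxon is not None and self.focal_taxon not in self.taxa:
            raise ValueError(f"focal taxon {self.focal_taxon!r} not in alignment")

    @classmethod
    def from_fasta(cls, path, focal_taxon=None) -> "ProteinAlignment":
        from .io import read_fasta
        seqs = read_fasta(path)
        return cls(list(seqs), list(seqs.values()), focal_taxon)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def find_exclusive_substitutions(aln: ProteinAlignment, focal_taxon: str = None):
    """Columns where only the focal taxon deviates from an invariant residue.

    A column is reported iff every non-focal row carries one identical
    non-gap residue and the focal row carries a different non-gap
    residue; columns containing any gap are skipped.  Returns a list of
    ``(column_1based, focal_residue, consensus_residue)``.
    """
    focal = focal_taxon or aln.focal_taxon
    if focal is None:
        raise ValueError("no focal taxon given")
    if len(aln.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    fi = aln.taxa.index(focal)
    others = [r for i, r in enumerate(aln.rows) if i != fi]
    out = []
    for c in range(aln.length):
        col = [r[c] for r in others]
        f = aln.rows[fi][c]
        if f in GAPS or any(x in GAPS for x in col):
            continue
        if len(set(col)) == 1 and col[0] != f:
            out.append((c + 1, f, col[0]))
    return out


def pairwise_identity_table(aln: ProteinAlignment) -> pd.DataFrame:
    """Percent identity over mutually ungapped columns, all taxa pairs."""
    n = len(aln.taxa)
    mat = np.full((n, n), 100.0)
    arrs = [np.frombuffer(r.encode(), np.uint8) for r in aln.rows]
    gap_masks = [np.isin(a, [ord("-"), ord(".")]) for a in arrs]
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap_masks[i] & ~gap_masks[j]
            if ok.sum() == 0:
                mat[i, j] = mat[j, i] = np.nan
                continue
            ident = 100.0 * (arrs[i][ok] == arrs[j][ok]).mean()
            mat[i, j] = mat[j, i] = ident
    return pd.DataFrame(mat, index=aln.taxa, columns=aln.taxa)
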