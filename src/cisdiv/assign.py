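"""Competitive allele assignment of reads in an allodiploid line.

Each read is aligned to both parental genomes and labelled by the allele
with the smaller alignment edit distance (substitutions + indels); equal
distances are ambiguous and excluded from per-allele counting.  Within
one genome, candidate loci are found with an exact k-mer seed index and
verified by banded edit-distance alignment of the full read (edlib),
keeping the minimum-edit locus with ties broken leftmost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np
import pandas as pd

from .simulate import revcomp


@dataclass(frozen=True)
class AlignmentHit:
    genome_id: str
    chrom: str
    start: int
    end: int
    edit_distance: int
    n_matches: int
    strand: str = "+"


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    best_a: Optional[AlignmentHit]
    best_b: Optional[AlignmentHit]
    label: str  # A | B | ambiguous | unmapped


class GenomeIndex:
    """Exact k-mer index over one genome's forward strand."""

    def __init__(self, seqs: dict, k: int = 12):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.k = k
        self.seqs = seqs
        self.index: dict = {}
        for chrom in sorted(seqs):
            s = seqs[chrom]
            for i in range(len(s) - k + 1):
                self.index.setdefault(s[i:i + k], []).append((chrom, i))

    def candidates(self, read: str, stride: int = None):
        """Candidate (chrom, diagonal-start) loci from exact seed matches."""
        k = self.k
        stride = stride or max(1, k // 2)
        out = set()
        for off in range(0, len(read) - k + 1, stride):
            for chrom, pos in self.index.get(read[off:off + k], ()):
                out.add((chrom, pos - off))
        return sorted(out)


def _cigar_matches(cigar: str) -> int:
    n = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch == "=":
                n += int(num)
            num = ""
    return n


def find_best_hit(read: str, index: GenomeIndex, genome_id: str,
                  max_edit: int = None) -> Optional[AlignmentHit]:
    """Best locus of ``read`` in one genome, or None if nothing <= max_edit.

    Both orientations are tried; ties between loci are broken leftmost
    (chrom lexicographic, then start).  Degenerate reads (shorter than
    the seed length) are unmapped with a warning.
    """
    if max_edit is None:
        max_edit = len(read) // 10
    if len(read) < index.k:
        warnings.warn(f"read shorter than seed length {index.k}; unmapped")
        return None
    best = None
    best_key = None
    for strand, oriented in (("+", read), ("-", revcomp(read))):
        for chrom, diag in index.candidates(oriented):
            lo = max(0, diag - max_edit)
            hi = min(len(index.seqs[chrom]), diag + len(oriented) + max_edit)
            window = index.seqs[chrom][lo:hi]
            res = edlib.align(oriented, window, mode="HW", task="path", k=max_edit)
            if res["editDistance"] < 0:
                continue
            s, e = res["locations"][0]
            hit = AlignmentHit(genome_id, chrom, lo + s, lo + e + 1,
                               res["editDistance"], _cigar_matches(res["cigar"]),
                               strand)
            key = (hit.edit_distance, hit.chrom, hit.start)
            if best_key is None or key < best_key:
                best, best_key = hit, key
    return best


def assign_read(best_a: Optional[AlignmentHit],
                best_b: Optional[AlignmentHit]) -> str:
    """Competitive label from the two per-genome best hits."""
    if best_a is None and best_b is None:
        return "unmapped"
    if best_b is None:
        return "A"
    if best_a is None:
        return "B"
    if best_a.edit_distance < best_b.edit_distance:
        return "A"
    if best_b.edit_distance < best_a.edit_distance:
        return "B"
    return "ambiguous"


def assign_reads(reads: pd.DataFrame, index_a: GenomeIndex, index_b: GenomeIndex,
                 max_edit: int = None) -> pd.DataFrame:
    """Assign every read; returns a tidy frame, one row per read.

    Columns: read_id, label, chrom, start, end, edit_a, edit_b (edit
    distances are -1 where the genome produced no hit; locus columns
    refer to the winning genome, or A on ambiguity for bookkeeping).
    """
    rows = []
    for rid, seq in zip(reads.read_id, reads.seq):
        ha = find_best_hit(seq, index_a, "A", max_edit)
        hb = find_best_hit(seq, index_b, "B", max_edit)
        label = assign_read(ha, hb)
        winner = ha if label in ("A", "ambiguous") else hb
        rows.append(dict(
            read_id=rid, label=label,
            chrom=winner.chrom if winner else ".",
            start=winner.start if winner else -1,
            end=winner.end if winner else -1,
            edit_a=ha.edit_distance if ha else -1,
            edit_b=hb.edit_distance if hb else -1,
        ))
    return pd.DataFrame(rows)


def count_features(assignments: pd.DataFrame, features: pd.DataFrame,
                   label: str, chroms=None) -> pd.Series:
    """Reads with the given allele label per feature, midpoint rule.

    A read increments a feature iff the midpoint of its hit interval lies
    within the feature interval; ambiguous and unmapped reads are never
    counted (callers pass label "A" or "B").  ``features`` has columns
    (chrom, start, end, name) on the labelled genome; ``chroms`` is that
    genome's chromosome set for validation.
    """
    if chroms is not None:
        unknown = set(features.chrom) - set(chroms)
        if unknown:
            raise ValueError(f"feature on unknown chromosome {sorted(unknown)[0]!r}")
    sub = assignments[assignments.label == label]
    counts = pd.Series(0, index=features.name, dtype=int)
    by_chrom = dict(tuple(features.groupby("chrom")))
    for chrom, grp in sub.groupby("chrom"):
        f = by_chrom.get(chrom)
        if f is None:
            continue
        mid = ((grp.start + grp.end) // 2).to_numpy()
        hit = ((mid[:, None] >= f.start.to_numpy()[None, :])
               & (mid[:, None] < f.end.to_numpy()[None, :]))
        counts[f.name.to_numpy()] += hit.sum(axis=0)
    return counts


def count_matrix(assignments: pd.DataFrame, features_a: pd.DataFrame,
                 features_b: pd.DataFrame, chroms_a=None, chroms_b=None) -> pd.DataFrame:
    """Per-feature per-allele counts, long format (name, allele, count)."""
    parts = []
    for label, feats, chroms in (("A", features_a, chroms_a),
                                 ("B", features_b, chroms_b)):
        s = count_features(assignments, feats, label, chroms)
        parts.append(pd.DataFrame({"name": s.index, "allele": label,
                                   "count": s.to_numpy()}))
    return pd.concat(parts, ignore_index=True)
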