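"""Cross-genome peak projection and orthology classification.

Each peak is reduced to a 400 bp window centred on its summit, aligned to
the other genome with a blat-style seeded aligner (11-mer exact seeds on
both strands, diagonal chaining, local-alignment extension), and the best
alignment is classified:

* ``unaligned`` — no alignment passes the identity/score/coverage filters;
* ``conserved`` — the aligned region covers more than half of a peak in
  the target genome (strict > 50% of the target peak's length);
* ``loss`` — alignable, but no target peak is covered that far.

Peaks whose second-best alignment is nearly as good as the best are
``multi_mapped`` and excluded from classification.  The extension stage
maximises matches − mismatches − gap_opens (match +1, mismatch −1, gap
open −1, gap extension 0), so the retained score is exactly that
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio import Align

from .simulate import revcomp

SEED_LEN = 11
_DIAG_BAND = 40       # max diagonal scatter within one chained cluster
_MIN_CLUSTER_SEEDS = 3
_MAX_CLUSTERS = 12    # extend only the most seed-rich clusters per strand
_PAD = 80             # window padding around a chained span before extension


@dataclass(frozen=True)
class MapHit:
    chrom: str
    strand: str
    t_start: int
    t_end: int
    q_start: int
    q_end: int
    matches: int
    mismatches: int
    gap_cols: int
    gap_opens: int
    query_len: int

    @property
    def score(self) -> int:
        return self.matches - self.mismatches - self.gap_opens

    @property
    def identity(self) -> float:
        denom = self.matches + self.mismatches
        return 100.0 * self.matches / denom if denom else 0.0

    @property
    def aligned_fraction(self) -> float:
        return (self.q_end - self.q_start) / self.query_len


class TargetIndex:
    """11-mer seed index with over-represented-seed masking."""

    def __init__(self, seqs: dict, k: int = SEED_LEN, max_occ: int = 24):
        self.k = k
        self.seqs = seqs
        idx: dict = {}
        for chrom in sorted(seqs):
            s = seqs[chrom]
            for i in range(len(s) - k + 1):
                idx.setdefault(s[i:i + k], []).append((chrom, i))
        # mask seeds occurring too often (blat's .ooc file analogue)
        self.index = {km: v for km, v in idx.items() if len(v) <= max_occ}


def extract_window(peak, genome_seqs: dict, halfwidth: int = 200):
    """400 bp summit-centred window [summit-200, summit+200), clipped.

    ``peak`` is a mapping with chrom/start/summit (summit = offset from
    start).  Returns ``(sequence, clipped_flag)``; a summit outside the
    chromosome raises.
    """
    chrom = peak["chrom"]
    seq = genome_seqs[chrom]
    summit = int(peak["start"]) + int(peak["summit"])
    if not (0 <= summit < len(seq)):
        raise ValueError(f"summit {summit} outside chromosome {chrom}")
    lo, hi = summit - halfwidth, summit + halfwidth
    clipped = lo < 0 or hi > len(seq)
    return seq[max(lo, 0):min(hi, len(seq))], clipped


# Search uses affine gap penalties so arbitrarily long gaps cannot be
# opened for free; the *retained* score is recomputed from the resulting
# path as matches - mismatches - gap_opens (see MapHit.score).
_ALIGNER = Align.PairwiseAligner(mode="local", match_score=1,
                                 mismatch_score=-1, open_gap_score=-2,
                                 extend_gap_score=-1)


def _extend(target: str, query: str, chrom: str, strand: str,
            t_off: int, qlen: int) -> Optional[MapHit]:
    """Local alignment of query vs a target window; stats from the path."""
    alns = _ALIGNER.align(target, query)
    if alns.score <= 0:
        return None
    aln = alns[0]  # one co-optimal path suffices for the retained statistics
    tb, qb = aln.aligned
    matches = mismatches = 0
    for (ts, te), (qs, qe) in zip(tb, qb):
        t_arr = np.frombuffer(target[ts:te].encode(), np.uint8)
        q_arr = np.frombuffer(query[qs:qe].encode(), np.uint8)
        eq = int((t_arr == q_arr).sum())
        matches += eq
        mismatches += (te - ts) - eq
    gap_cols = gap_opens = 0
    for i in range(1, len(tb)):
        tg = int(tb[i][0] - tb[i - 1][1])
        qg = int(qb[i][0] - qb[i - 1][1])
        gap_cols += tg + qg
        gap_opens += (tg > 0) + (qg > 0)
    q_start, q_end = int(qb[0][0]), int(qb[-1][1])
    if strand == "-":
        q_start, q_end = qlen - q_end, qlen - q_start
    return MapHit(chrom, strand, t_off + int(tb[0][0]), t_off + int(tb[-1][1]),
                  q_start, q_end, matches, mismatches, gap_cols, gap_opens, qlen)


def seeded_align(query: str, index: TargetIndex, min_identity: float = 70.0,
                 min_score: int = 100) -> list:
    """Blat-style alignment of a peak window to the other genome.

    Returns qualifying :class:`MapHit` objects sorted by score
    descending.  Queries shorter than 50 bp are rejected.
    """
    if len(query) < 50:
        raise ValueError("query must be >= 50 bp")
    k = index.k
    hits = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        seeds = {}
        for off in range(0, len(q) - k + 1):
            for chrom, pos in index.index.get(q[off:off + k], ()):
                seeds.setdefault(chrom, []).append(pos - off)
        clusters = []
        for chrom, diags in seeds.items():
            diags = np.sort(np.asarray(diags))
            # cluster diagonals separated by more than the band
            breaks = np.flatnonzero(np.diff(diags) > _DIAG_BAND)
            for grp in np.split(diags, breaks + 1):
                if grp.size >= _MIN_CLUSTER_SEEDS:
                    clusters.append((chrom, grp))
        clusters.sort(key=lambda cg: -cg[1].size)
        for chrom, grp in clusters[:_MAX_CLUSTERS]:
            t_lo = max(0, int(grp[0]) - _PAD)
            t_hi = min(len(index.seqs[chrom]), int(grp[-1]) + len(q) + _PAD)
            hit = _extend(index.seqs[chrom][t_lo:t_hi], q, chrom, strand,
                          t_lo, len(query))
            if hit is not None:
                hits.append(hit)
    hits = _dedupe(hits)
    hits = [h for h in hits if h.identity >= min_identity and h.score >= min_score]
    return sorted(hits, key=lambda h: (-h.score, h.chrom, h.t_start))


def _dedupe(hits: list) -> list:
    """Suppress hits overlapping a better hit at the same target locus."""
    kept = []
    for h in sorted(hits, key=lambda h: -h.score):
        dup = any(k.chrom == h.chrom
                  and min(k.t_end, h.t_end) - max(k.t_start, h.t_start)
                  > 0.5 * (h.t_end - h.t_start)
                  for k in kept)
        if not dup:
            kept.append(h)
    return kept


def best_hit_filter(hits: list, min_aligned_fraction: float = 0.7,
                    single_hit_ratio: float = 0.95):
    """Coverage filter plus near-tie multi-mapping exclusion.

    Returns ``(status, best_hit_or_None)`` with status one of single_hit,
    multi_mapped, no_hit.
    """
    hits = [h for h in hits if h.aligned_fraction >= min_aligned_fraction]
    if not hits:
        return "no_hit", None
    if len(hits) >= 2 and hits[1].score >= single_hit_ratio * hits[0].score:
        return "multi_mapped", None
    return "single_hit", hits[0]


def classify_peak(status: str, best: Optional[MapHit],
                  target_peaks: pd.DataFrame) -> Optional[str]:
    """conserved / loss / unaligned from the filtered best alignment.

    Conserved requires the aligned target interval to cover strictly more
    than 50% of the length of some target-genome peak; multi-mapped peaks
    return None (excluded).
    """
    if status == "multi_mapped":
        return None
    if status == "no_hit":
        return "unaligned"
    tp = target_peaks[target_peaks.chrom == best.chrom]
    if len(tp):
        ov = (np.minimum(tp.end.to_numpy(), best.t_end)
              - np.maximum(tp.start.to_numpy(), best.t_start))
        lengths = (tp.end - tp.start).to_numpy()
        if (ov > 0.5 * lengths).any():
            return "conserved"
    return "loss"


def matched_bases(status: str, best: Optional[MapHit]) -> int:
    """Identical aligned bases of the best hit; 0 when nothing aligned."""
    return best.matches if status == "single_hit" and best is not None else 0


def project_peaks(peaks: pd.DataFrame, source_seqs: dict, index: TargetIndex,
                  target_peaks: pd.DataFrame, min_identity: float = 70.0,
                  min_score: int = 100, min_aligned_fraction: float = 0.7,
                  single_hit_ratio: float = 0.95,
                  window_halfwidth: int = 200) -> pd.DataFrame:
    """Project and classify every peak of one genome against the other.

    Returns one row per source peak: name, status, klass, target locus,
    matches, mismatches, identity, aligned_fraction, score,
    matched_bases.
    """
    rows = []
    for _, pk in peaks.iterrows():
        window, _ = extract_window(pk, source_seqs, window_halfwidth)
        hits = seeded_align(window, index, min_identity, min_score)
        status, best = best_hit_filter(hits, min_aligned_fraction,
                                       single_hit_ratio)
        klass = classify_peak(status, best, target_peaks)
        rows.append(dict(
            name=pk["name"], status=status,
            klass=klass if klass is not None else "NA",
            t_chrom=best.chrom if best else ".",
            t_start=best.t_start if best else -1,
            t_end=best.t_end if best else -1,
            strand=best.strand if best else ".",
            matches=best.matches if best else 0,
            mismatches=best.mismatches if best else 0,
            identity=round(best.identity, 3) if best else 0.0,
            aligned_fraction=round(best.aligned_fraction, 4) if best else 0.0,
            score=best.score if best else 0,
            matched_bases=matched_bases(status, best),
        ))
    return pd.DataFrame(rows)


def class_counts(projection: pd.DataFrame) -> pd.Series:
    """Counts of conserved/loss/unaligned/multi_mapped (exact partition)."""
    klass = projection.klass.where(projection.status != "multi_mapped",
                                   "multi_mapped")
    return klass.value_counts().reindex(
        ["conserved", "loss", "unaligned", "multi_mapped"], fill_value=0)
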