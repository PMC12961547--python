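"""Count normalisation and threshold rules for differential signal.

Implements the pipeline's declared calling rules: the high-confidence
peak filter (-log10 q strictly above 4), the accessibility UP/DOWN/COMMON
rule (|log2 fold change| > 1 with a floor on total normalised counts),
and the allele-stronger binding call at a fold-change threshold of 2.
Library scaling is total-count scaling to the mean library size; a
pseudocount of 1 is applied before any log ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def library_normalise(counts: pd.DataFrame, cols) -> pd.DataFrame:
    """Scale each sample column to the mean library size.

    Preserves within-sample count ratios exactly (a single multiplicative
    factor per column).
    """
    out = counts.copy()
    totals = counts[list(cols)].sum(axis=0).astype(float)
    target = totals.mean()
    for c in cols:
        out[c] = counts[c] * (target / totals[c] if totals[c] > 0 else 1.0)
    return out


def filter_high_confidence(peaks: pd.DataFrame,
                           min_neglog10_q: float = 4.0) -> pd.DataFrame:
    """Keep peaks with -log10(q) strictly greater than the cutoff."""
    return peaks[peaks.qvalue > min_neglog10_q].reset_index(drop=True)


def log2fc(n1, n2, pseudocount: float = 1.0):
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 < 0).any() or (n2 < 0).any():
        raise ValueError("negative counts")
    return np.log2((n1 + pseudocount) / (n2 + pseudocount))


def classify_atac(norm1, norm2, fc_thresh: float = 1.0, min_total: float = 40.0,
                  pseudocount: float = 1.0):
    """UP/DOWN/COMMON per feature from a normalised count pair.

    UP means condition 1 exceeds condition 2 by more than ``fc_thresh``
    in log2 with total normalised counts at least ``min_total``; DOWN is
    symmetric; everything else is COMMON.
    """
    fc = log2fc(norm1, norm2, pseudocount)
    total = np.asarray(norm1, float) + np.asarray(norm2, float)
    out = np.where((fc > fc_thresh) & (total >= min_total), "UP",
                   np.where((fc < -fc_thresh) & (total >= min_total), "DOWN",
                            "COMMON"))
    return out if out.ndim else str(out)


def classify_chip_stronger(norm_a, norm_b, fold: float = 2.0,
                           pseudocount: float = 1.0):
    """A_stronger / B_stronger / similar at a fold-change threshold."""
    a = np.asarray(norm_a, float) + pseudocount
    b = np.asarray(norm_b, float) + pseudocount
    out = np.where(a >= fold * b, "A_stronger",
                   np.where(b >= fold * a, "B_stronger", "similar"))
    return out if out.ndim else str(out)


def signal_matrix(read_mids: pd.DataFrame, sites: pd.DataFrame,
                  flank: int = 2000, bin_width: int = 100) -> pd.DataFrame:
    """Summit-centred binned read-midpoint density, one row per site.

    ``read_mids`` has columns (chrom, mid); ``sites`` has chrom/start/
    summit/name.  Densities are scaled to reads per million; rows are
    ordered by total signal descending.
    """
    n_bins = 2 * flank // bin_width
    edges = np.arange(-flank, flank + bin_width, bin_width)
    total_reads = max(len(read_mids), 1)
    by_chrom = {c: np.sort(g.mid.to_numpy()) for c, g in read_mids.groupby("chrom")}
    mat = np.zeros((len(sites), n_bins))
    names = []
    for i, (_, st) in enumerate(sites.iterrows()):
        names.append(st["name"])
        mids = by_chrom.get(st["chrom"])
        if mids is None:
            continue
        summit = int(st["start"]) + int(st["summit"])
        mat[i], _ = np.histogram(mids - summit, bins=edges)
    mat *= 1e6 / total_reads
    df = pd.DataFrame(mat, index=pd.Index(names, name="name"),
                      columns=[f"bin_{int(e)}" for e in edges[:-1]])
    return df.loc[df.sum(axis=1).sort_values(ascending=False, kind="stable").index]
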