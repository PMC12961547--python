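"""Peak-to-gene linkage via a TSS-centred window.

A peak is linked to a gene when its summit falls inside a 60 kb window
centred on the gene's strand-aware transcription start site (half-open,
clipped to chromosome bounds).  Per regulation type, the composition of
linked peaks over the three orthology classes summarises how binding
divergence relates to expression divergence; the one-gene opposite-
response type is excluded from that table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CLASS_ORDER = ["conserved", "loss", "unaligned"]


def gene_windows(genes: pd.DataFrame, window: int = 60_000,
                 chrom_lengths: dict = None) -> pd.DataFrame:
    """Attach [tss - window/2, tss + window/2) bounds to each gene."""
    half = window // 2
    out = genes.copy()
    out["win_start"] = (out.tss - half).clip(lower=0)
    out["win_end"] = out.tss + half
    if chrom_lengths:
        out["win_end"] = [min(e, chrom_lengths.get(c, e))
                          for e, c in zip(out.win_end, out.chrom)]
    return out


def link(genes: pd.DataFrame, peaks: pd.DataFrame, window: int = 60_000,
         chrom_lengths: dict = None) -> pd.DataFrame:
    """Link peaks to genes by summit-in-window containment.

    ``genes`` columns: gene_id, chrom, tss, strand.  ``peaks`` columns:
    chrom, start, summit (offset), name, and optionally klass.  A peak
    may link to several genes.  Returns (gene_id, name, klass).
    """
    gw = gene_windows(genes, window, chrom_lengths)
    pk = peaks.copy()
    pk["summit_abs"] = pk.start + pk.summit
    rows = []
    for chrom, genes_c in gw.groupby("chrom"):
        pc = pk[pk.chrom == chrom]
        if pc.empty:
            continue
        s = pc.summit_abs.to_numpy()
        for _, g in genes_c.iterrows():
            inside = (s >= g.win_start) & (s < g.win_end)
            for _, p in pc[inside].iterrows():
                rows.append(dict(gene_id=g.gene_id, name=p["name"],
                                 klass=p.get("klass", "NA")))
    return pd.DataFrame(rows, columns=["gene_id", "name", "klass"])


def class_composition_by_type(links: pd.DataFrame, gene_types: pd.DataFrame,
                              types=(0, 1, 3, 4)) -> pd.DataFrame:
    """Orthology-class proportions of linked peaks per regulation type.

    ``gene_types`` maps gene_id -> type.  Rows are the requested types
    (the opposite-response type is excluded by default); a type with no
    linked classified peaks yields a NaN row, not zeros.  Non-empty rows
    sum to 1.
    """
    merged = links.merge(gene_types[["gene_id", "type"]], on="gene_id")
    merged = merged[merged.klass.isin(CLASS_ORDER)]
    rows = {}
    for t in types:
        sub = merged[merged.type == t]
        if len(sub) == 0:
            rows[t] = pd.Series(np.nan, index=CLASS_ORDER)
        else:
            rows[t] = (sub.klass.value_counts(normalize=True)
                       .reindex(CLASS_ORDER, fill_value=0.0))
    out = pd.DataFrame(rows).T
    out.index.name = "type"
    return out
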