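"""Allele-specific expression response typing.

For each homolog pair (one gene copy per parental allele, sharing the
nuclear trans environment), the per-allele response to TF induction is
called from count fold changes and the pair is placed in one of five
regulation types:

====  ==========================================
type  allele response pattern
====  ==========================================
0     no change on either allele
1     change only on allele A (mouse-like)
2     opposite-direction changes on the two alleles
3     change only on allele B (rat-like)
4     same-direction change on both alleles
====  ==========================================

The Welch t comparison of response magnitudes across types and the
Pearson correlation of sample transcriptomes are implemented from their
defining formulas (scipy supplies only the t-distribution tail).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffsignal import log2fc

TYPE_LABELS = {0: "no_change", 1: "allele_A_only", 2: "opposite",
               3: "allele_B_only", 4: "concordant"}


def call_response(ctrl, induced, fc_thresh: float = 1.0,
                  expr_floor: float = 3.0, pseudocount: float = 1.0):
    """Per-allele response call: up / down / none.

    A call requires the allele to pass the expression floor in at least
    one condition and the |log2 fold change| (with pseudocount) to exceed
    ``fc_thresh``.  Returns ``(log2fc, expressed, call)`` arrays.
    """
    ctrl = np.asarray(ctrl, dtype=float)
    induced = np.asarray(induced, dtype=float)
    fc = log2fc(induced, ctrl, pseudocount)
    expressed = (ctrl > expr_floor) | (induced > expr_floor)
    call = np.where(~expressed, "none",
                    np.where(fc > fc_thresh, "up",
                             np.where(fc < -fc_thresh, "down", "none")))
    return fc, expressed, call


_CALL_SIGN = {"up": 1, "down": -1, "none": 0}


def assign_type(call_a: str, call_b: str) -> int:
    """Five-way regulation type from the two allele calls (total mapping)."""
    sa, sb = _CALL_SIGN[call_a], _CALL_SIGN[call_b]
    if sa == 0 and sb == 0:
        return 0
    if sb == 0:
        return 1
    if sa == 0:
        return 3
    return 4 if sa == sb else 2


def type_genes(expr: pd.DataFrame, fc_thresh: float = 1.0,
               expr_floor: float = 3.0, pseudocount: float = 1.0) -> pd.DataFrame:
    """Call both alleles and type every candidate homolog pair.

    ``expr`` columns: pair_id, a_ctrl, a_dox, b_ctrl, b_dox (replicates,
    if any, averaged upstream).  Candidates are pairs where both alleles
    pass the expression floor in at least one condition; non-candidates
    are returned with type -1.
    """
    fa, ea, ca = call_response(expr.a_ctrl, expr.a_dox, fc_thresh,
                               expr_floor, pseudocount)
    fb, eb, cb = call_response(expr.b_ctrl, expr.b_dox, fc_thresh,
                               expr_floor, pseudocount)
    candidate = ea & eb
    types = np.array([assign_type(x, y) for x, y in zip(ca, cb)])
    types = np.where(candidate, types, -1)
    return pd.DataFrame({
        "pair_id": expr.pair_id, "log2fc_a": fa, "log2fc_b": fb,
        "call_a": ca, "call_b": cb, "candidate": candidate, "type": types,
    })


def type_counts(typed: pd.DataFrame) -> pd.Series:
    """Counts of types 0..4 among candidate pairs."""
    t = typed.loc[typed.type >= 0, "type"]
    return t.value_counts().reindex(range(5), fill_value=0)


def welch_t(x, y):
    """Welch two-sample t on the defining formulas.

    Returns ``(t, p, df)`` with the two-sided p from the t distribution.
    Identical degenerate groups give t=0, p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / x.size + vy / y.size
    if se2 == 0:
        return (0.0, 1.0, float(x.size + y.size - 2))
    t = (mx - my) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / x.size) ** 2 / (x.size - 1)
                     + (vy / y.size) ** 2 / (y.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), float(df)


def magnitude_test(typed: pd.DataFrame, type_x: int, type_y: int,
                   allele: str = "a"):
    """Welch t on |log2FC| between two regulation types for one allele."""
    col = f"log2fc_{allele}"
    gx = typed.loc[typed.type == type_x, col].abs().to_numpy()
    gy = typed.loc[typed.type == type_y, col].abs().to_numpy()
    return welch_t(gx, gy)


def expression_correlation(x, y):
    """Pearson r with two-sided p via the t transform (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors, n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    r = float((xd * yd).sum() / np.sqrt((xd ** 2).sum() * (yd ** 2).sum()))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))
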