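"""Position-weight-matrix scanning with exact score-distribution p-values.

The scanner mirrors FIMO's model: windows of length w are scored with a
log2-odds matrix against a 0-order background, on both strands, and a
window's p-value is the exact tail probability of its score under the
background model.  The score distribution is computed by dynamic
programming over scores discretised to 1/100 bit; a window's own score is
discretised with the same rule before lookup, so DP p-values are exact
for the discretised score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
_DISCRETISE = 100  # score bins per bit


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N) -> -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), np.uint8) == ord(b)] = i
    return out


@dataclass
class PWM:
    """A probability PWM with background model and pseudocount.

    ``probs`` is width x 4 (A, C, G, T).  Rows are renormalised with
    ``pseudocount`` times the background added, as FIMO does.
    """

    probs: np.ndarray
    background: np.ndarray = None
    pseudocount: float = 0.1
    name: str = "motif"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        adj = self.probs + self.pseudocount * self.background
        self.probs = adj / adj.sum(axis=1, keepdims=True)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1 after normalisation")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def int_scores(self) -> np.ndarray:
        """log-odds discretised to 1/100 bit (integers)."""
        return np.rint(self.log_odds * _DISCRETISE).astype(np.int64)

    def consensus_codes(self) -> np.ndarray:
        return self.probs.argmax(axis=1)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.consensus_codes())

    def reverse_complement(self) -> "PWM":
        rc = PWM.__new__(PWM)
        rc.probs = self.probs[::-1, ::-1].copy()
        rc.background = self.background[::-1].copy()
        rc.pseudocount = self.pseudocount
        rc.name = self.name
        return rc

    # -- MEME text format ---------------------------------------------------

    @classmethod
    def from_meme(cls, path_or_text, pseudocount: float = 0.1) -> "PWM":
        """Parse the first motif of a MEME-format text file (or string)."""
        text = path_or_text
        if "\n" not in str(path_or_text):
            with open(path_or_text) as fh:
                text = fh.read()
        lines = text.splitlines()
        background = None
        name = "motif"
        rows = []
        it = iter(range(len(lines)))
        for i in it:
            line = lines[i].strip()
            if line.startswith("Background letter frequencies"):
                vals = lines[i + 1].split()
                background = np.array([float(vals[j]) for j in (1, 3, 5, 7)])
            elif line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                w = None
                for tok_i, tok in enumerate(line.replace("=", " = ").split()):
                    if tok == "w":
                        w = int(line.replace("=", " = ").split()[tok_i + 2])
                j = i + 1
                while len(rows) < (w or 10 ** 9) and j < len(lines):
                    parts = lines[j].split()
                    if len(parts) != 4:
                        break
                    rows.append([float(x) for x in parts])
                    j += 1
                break
        if not rows:
            raise ValueError("no letter-probability matrix found")
        return cls(np.array(rows), background=background,
                   pseudocount=pseudocount, name=name)


# ---------------------------------------------------------------------------
# scanning


def score_distribution(pwm: PWM) -> tuple[np.ndarray, int]:
    """Exact background distribution of discretised window scores.

    Returns ``(pmf, offset)``: ``pmf[k]`` is the probability of integer
    score ``k + offset`` for a random background window.
    """
    ints = pwm.int_scores
    lo = int(ints.min(axis=1).sum())
    hi = int(ints.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # column-by-column convolution of the 4-point column distributions
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(pwm.width):
        col = ints[i]
        clo, chi = int(col.min()), int(col.max())
        nxt = np.zeros(cur.size + chi - clo)
        for b in range(4):
            nxt[col[b] - clo:col[b] - clo + cur.size] += pwm.background[b] * cur
        cur = nxt
        cur_lo += clo
    pmf[cur_lo - lo:cur_lo - lo + cur.size] = cur
    return pmf, lo


def pvalue_table(pwm: PWM) -> tuple[np.ndarray, int]:
    """Tail probabilities: ``tail[k]`` = P(score >= k + offset)."""
    pmf, lo = score_distribution(pwm)
    return np.cumsum(pmf[::-1])[::-1], lo


def _window_int_scores(codes: np.ndarray, ints: np.ndarray) -> np.ndarray:
    """Sum of per-column integer scores for every window; N scores 0."""
    w = ints.shape[0]
    n_win = codes.size - w + 1
    out = np.zeros(n_win, dtype=np.int64)
    for i in range(w):
        c = codes[i:i + n_win]
        valid = c >= 0
        out[valid] += ints[i][c[valid]]
    return out


def _window_float_scores(codes: np.ndarray, lodds: np.ndarray) -> np.ndarray:
    w = lodds.shape[0]
    n_win = codes.size - w + 1
    out = np.zeros(n_win)
    for i in range(w):
        c = codes[i:i + n_win]
        valid = c >= 0
        out[valid] += lodds[i][c[valid]]
    return out


def scan(sequence: str, pwm: PWM, p_threshold: float = 1e-4) -> pd.DataFrame:
    """Scan both strands; return hits with p <= ``p_threshold``.

    Columns: position (window start on the forward sequence), strand,
    score (log2 odds), pvalue.  A minus-strand hit at position p means
    the reverse complement of sequence[p:p+w] matches.
    """
    if len(sequence) < pwm.width:
        raise ValueError("sequence shorter than PWM width")
    codes = encode(sequence.upper())
    tail, lo = pvalue_table(pwm)

    rows = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        ints = mat.int_scores
        f = _window_float_scores(codes, mat.log_odds)
        s = _window_int_scores(codes, ints)
        idx = np.clip(s - lo, 0, tail.size - 1)
        p = tail[idx]
        p = np.where(s - lo < 0, 1.0, p)
        keep = p <= p_threshold
        for pos in np.flatnonzero(keep):
            rows.append((int(pos), strand, float(f[pos]), float(p[pos])))
    df = pd.DataFrame(rows, columns=["position", "strand", "score", "pvalue"])
    return df.sort_values(["position", "strand"], ignore_index=True)


def has_hit(sequence: str, pwm: PWM, p_threshold: float = 1e-4) -> bool:
    if len(sequence) < pwm.width:
        return False
    return len(scan(sequence, pwm, p_threshold)) > 0


def motif_fraction_by_class(window_seqs: dict, klass_by_peak: dict, pwm: PWM,
                            p_threshold: float = 1e-4) -> pd.Series:
    """Fraction of peaks in each orthology class with at least one motif hit.

    ``window_seqs`` maps peak name -> window sequence; ``klass_by_peak``
    maps peak name -> conserved/loss/unaligned.  Peaks without a class
    (multi-mapped) are ignored.
    """
    counts, hits = {}, {}
    for name, seq in window_seqs.items():
        k = klass_by_peak.get(name)
        if k is None:
            continue
        counts[k] = counts.get(k, 0) + 1
        if has_hit(seq, pwm, p_threshold):
            hits[k] = hits.get(k, 0) + 1
    return pd.Series({k: hits.get(k, 0) / counts[k] for k in sorted(counts)},
                     name="motif_fraction")
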