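"""Synthetic allodiploid data generator.

Builds a pair of related genomes (allele A and allele B) with a known
base-level homology map, plants TF-binding peaks in three cross-genome
orthology classes (conserved / loss / unaligned), draws ChIP-style reads
enriched around planted summits, and simulates per-allele expression
responses to TF induction under the five regulation types.  Every output
is accompanied by a truth table so downstream stages can be scored.

Genome B is genome A mutated at ``subst_rate`` with geometric-length
indels at ``indel_rate``; on top of that each genome receives
lineage-specific blocks of i.i.d. random sequence (insertions absent from
the other genome) that host the "unaligned" peak class.  The homology map
records every aligned column, so any simulated position can be projected
exactly between the alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig, SizingError, stage_rng

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")

CLASSES = ("conserved", "loss", "unaligned")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# genome pair


@dataclass
class AlleleGenomePair:
    """Two parental genomes plus the truth homology map.

    Sequences are stored as uint8 ASCII arrays (mutable, so peaks can be
    planted in place).  ``coord_map[chrom]`` is a pair of strictly
    increasing position arrays ``(a_pos, b_pos)``: column i says base
    ``a_pos[i]`` of A is homologous to base ``b_pos[i]`` of B.
    Lineage-specific blocks (per genome, per chrom) never appear in the
    map.
    """

    chroms: list
    a: dict
    b: dict
    coord_map: dict
    blocks_a: dict = field(default_factory=dict)
    blocks_b: dict = field(default_factory=dict)

    def seq(self, genome: str, chrom: str) -> str:
        arr = (self.a if genome == "A" else self.b)[chrom]
        return arr.tobytes().decode()

    def chrom_len(self, genome: str, chrom: str) -> int:
        return (self.a if genome == "A" else self.b)[chrom].size

    def map_pos(self, chrom: str, pos: int, src: str = "A"):
        """Project an exact homologous column src->other; None if unaligned."""
        a_pos, b_pos = self.coord_map[chrom]
        f, t = (a_pos, b_pos) if src == "A" else (b_pos, a_pos)
        i = np.searchsorted(f, pos)
        if i < f.size and f[i] == pos:
            return int(t[i])
        return None

    def map_nearest(self, chrom: str, pos: int, src: str = "A"):
        """Project to the nearest homologous column; (other_pos, offset)."""
        a_pos, b_pos = self.coord_map[chrom]
        f, t = (a_pos, b_pos) if src == "A" else (b_pos, a_pos)
        i = np.clip(np.searchsorted(f, pos), 0, f.size - 1)
        return int(t[i]), int(pos - f[i])

    def genomes_fasta(self, path_a, path_b):
        from . import io
        io.write_fasta(path_a, {c: self.seq("A", c) for c in self.chroms})
        io.write_fasta(path_b, {c: self.seq("B", c) for c in self.chroms})


def _mutate_chrom(a_idx, cfg: SimConfig, rng):
    """Derive allele-B core from allele-A core; return (b_idx, a_cols, b_cols)."""
    n = a_idx.size
    b_core = a_idx.copy()
    sub = rng.random(n) < cfg.subst_rate
    nsub = int(sub.sum())
    if nsub:
        b_core[sub] = (b_core[sub] + rng.integers(1, 4, nsub, dtype=np.uint8)) % 4
    ev_pos = np.flatnonzero(rng.random(n) < cfg.indel_rate)
    is_ins = rng.random(ev_pos.size) < 0.5
    if ev_pos.size:
        lens = rng.geometric(1.0 / max(cfg.mean_indel_len, 1.0), ev_pos.size)
    else:
        lens = np.empty(0, dtype=int)
    segs, a_cols, b_cols = [], [], []
    a = b = 0
    for pos, ins, ln in zip(ev_pos, is_ins, lens):
        if pos < a:  # inside a previous deletion
            continue
        seg = b_core[a:pos]
        segs.append(seg)
        a_cols.append(np.arange(a, pos, dtype=np.int64))
        b_cols.append(np.arange(b, b + seg.size, dtype=np.int64))
        b += seg.size
        a = pos
        if ins:
            segs.append(rng.integers(0, 4, ln, dtype=np.uint8))
            b += int(ln)
        else:
            a = min(a + int(ln), n)
    seg = b_core[a:]
    segs.append(seg)
    a_cols.append(np.arange(a, n, dtype=np.int64))
    b_cols.append(np.arange(b, b + seg.size, dtype=np.int64))
    b_idx = np.concatenate(segs) if segs else np.empty(0, np.uint8)
    return b_idx, np.concatenate(a_cols), np.concatenate(b_cols)


def _insert_blocks(seq_idx, pos_arrays, n_blocks, block_len, margin, rng):
    """Splice random blocks into a genome; shift map columns accordingly.

    Returns (new_seq, shifted_pos_arrays, block_intervals_in_new_coords).
    """
    n = seq_idx.size
    if n_blocks == 0:
        return seq_idx, pos_arrays, []
    lo, hi = margin, n - margin
    if hi <= lo:
        raise SizingError("chromosome too short for lineage-specific blocks")
    points = np.sort(rng.integers(lo, hi, n_blocks))
    pieces, blocks = [], []
    prev = 0
    for k, p in enumerate(points):
        pieces.append(seq_idx[prev:p])
        start = p + k * block_len
        pieces.append(_ASCII_IDX(rng, block_len))
        blocks.append((start, start + block_len))
        prev = p
    pieces.append(seq_idx[prev:])
    new_seq = np.concatenate(pieces)
    shifted = [pos + block_len * np.searchsorted(points, pos, side="right")
               for pos in pos_arrays]
    return new_seq, shifted, blocks


def _ASCII_IDX(rng, n):
    return rng.integers(0, 4, n, dtype=np.uint8)


def simulate_genome_pair(cfg: SimConfig) -> AlleleGenomePair:
    """Simulate the two parental genomes and their homology map.

    A pure function of ``cfg`` (including ``cfg.seed``): calling it twice
    with the same config yields identical sequences and maps.
    """
    rng = stage_rng(cfg.seed, "genome")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom_per_genome)]
    # distribute per-genome lineage blocks round-robin over chromosomes
    per_chrom = np.zeros(cfg.n_chrom_per_genome, dtype=int)
    for i in range(cfg.n_unalignable_blocks):
        per_chrom[i % cfg.n_chrom_per_genome] += 1

    a, b, cmap, blocks_a, blocks_b = {}, {}, {}, {}, {}
    margin = 2 * cfg.window_halfwidth + cfg.block_length
    for ci, chrom in enumerate(chroms):
        a_core = _ASCII_IDX(rng, cfg.chrom_length)
        b_core, a_cols, b_cols = _mutate_chrom(a_core, cfg, rng)
        nb = int(per_chrom[ci])
        a_seq, (a_cols,), blk_a = _insert_blocks(a_core, [a_cols], nb,
                                                 cfg.block_length, margin, rng)
        b_seq, (b_cols,), blk_b = _insert_blocks(b_core, [b_cols], nb,
                                                 cfg.block_length, margin, rng)
        a[chrom] = _ASCII[a_seq]
        b[chrom] = _ASCII[b_seq]
        cmap[chrom] = (a_cols, b_cols)
        blocks_a[chrom] = blk_a
        blocks_b[chrom] = blk_b
    return AlleleGenomePair(chroms, a, b, cmap, blocks_a, blocks_b)


# ---------------------------------------------------------------------------
# peaks

_PEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
              "signal", "pvalue", "qvalue", "summit"]


def _peak_row(chrom, summit_abs, name, hw, signal, qv):
    start = summit_abs - hw
    return dict(chrom=chrom, start=start, end=summit_abs + hw, name=name,
                score=int(min(1000, 10 * qv)), strand=".", signal=signal,
                pvalue=qv + 1.0, qvalue=qv, summit=summit_abs - start)


def _write_motif(seq_arr, start, consensus_codes):
    seq_arr[start:start + consensus_codes.size] = _ASCII[consensus_codes]


def plant_peaks(pair: AlleleGenomePair, pwm, cfg: SimConfig):
    """Plant consensus binding sites in three orthology classes.

    conserved: the PWM consensus written at homologous positions of both
    genomes, a peak emitted in each.  loss: consensus in one genome only;
    the homologous region exists in the other but carries no peak.
    unaligned: consensus inside a lineage-specific block.  Loss and
    unaligned peaks are planted symmetrically, ``n_peaks_loss`` /
    ``n_peaks_unaligned`` in each genome, so both projection directions
    see the same planted class counts.

    Returns ``(peaks_a, peaks_b, peak_truth)`` where the peak frames are
    narrowPeak-style DataFrames (summit stored as offset from start) and
    ``peak_truth`` maps peak name -> planted class.
    """
    rng = stage_rng(cfg.seed, "peaks")
    cons = np.asarray(pwm.consensus_codes(), dtype=np.uint8)
    w = cons.size
    hw, whw = cfg.peak_halfwidth, cfg.window_halfwidth
    guard = 2 * whw + 50  # min spacing between planted summits
    occupied = {"A": {c: [] for c in pair.chroms}, "B": {c: [] for c in pair.chroms}}

    def clashes(genome, chrom, pos):
        return any(pos - guard < e and pos + guard > s
                   for s, e in occupied[genome][chrom])

    def in_block(genome, chrom, pos, pad):
        blocks = (pair.blocks_a if genome == "A" else pair.blocks_b)[chrom]
        return any(pos + pad > s and pos - pad < e for s, e in blocks)

    def sample_homologous_site():
        """A homologous column pair with clear flanks in both genomes."""
        for _ in range(2000):
            chrom = pair.chroms[rng.integers(len(pair.chroms))]
            a_pos, b_pos = pair.coord_map[chrom]
            j = int(rng.integers(whw + 50, a_pos.size - whw - 50))
            pa, pb = int(a_pos[j]), int(b_pos[j])
            if (pa < guard or pa > pair.chrom_len("A", chrom) - guard or
                    pb < guard or pb > pair.chrom_len("B", chrom) - guard):
                continue
            if clashes("A", chrom, pa) or clashes("B", chrom, pb):
                continue
            if in_block("A", chrom, pa, guard) or in_block("B", chrom, pb, guard):
                continue
            return chrom, pa, pb
        raise SizingError("could not place a peak without overlap; "
                          "increase chrom_length or reduce peak counts")

    rows = {"A": [], "B": []}
    truth = {}

    def occupy(chrom, pa, pb):
        occupied["A"][chrom].append((pa - guard, pa + guard))
        occupied["B"][chrom].append((pb - guard, pb + guard))

    for i in range(cfg.n_peaks_conserved):
        chrom, pa, pb = sample_homologous_site()
        occupy(chrom, pa, pb)
        _write_motif(pair.a[chrom], pa - w // 2, cons)
        _write_motif(pair.b[chrom], pb - w // 2, cons)
        qa, qb = rng.uniform(5, 50, 2)
        na, nb = f"pk_cons_{i:04d}_A", f"pk_cons_{i:04d}_B"
        rows["A"].append(_peak_row(chrom, pa, na, hw, rng.uniform(5, 50), qa))
        rows["B"].append(_peak_row(chrom, pb, nb, hw, rng.uniform(5, 50), qb))
        truth[na] = "conserved"
        truth[nb] = "conserved"

    for genome in ("A", "B"):
        seqs = pair.a if genome == "A" else pair.b
        other_seqs = pair.b if genome == "A" else pair.a
        for i in range(cfg.n_peaks_loss):
            chrom, pa, pb = sample_homologous_site()
            occupy(chrom, pa, pb)
            here, there = (pa, pb) if genome == "A" else (pb, pa)
            if rng.random() >= cfg.loss_motif_ablation:
                _write_motif(seqs[chrom], here - w // 2, cons)
            if cfg.loss_extra_mut_rate > 0:
                lo = there - whw
                seg = other_seqs[chrom][lo:there + whw]
                hit = rng.random(seg.size) < cfg.loss_extra_mut_rate
                nhit = int(hit.sum())
                if nhit:
                    idx = np.searchsorted(_ASCII, seg[hit])
                    seg[hit] = _ASCII[(idx + rng.integers(1, 4, nhit)) % 4]
            name = f"pk_loss_{genome}_{i:04d}"
            rows[genome].append(_peak_row(chrom, here, name, hw, rng.uniform(5, 50),
                                          rng.uniform(5, 50)))
            truth[name] = "loss"

    for genome in ("A", "B"):
        seqs = pair.a if genome == "A" else pair.b
        blocks = pair.blocks_a if genome == "A" else pair.blocks_b
        flat = [(c, s, e) for c in pair.chroms for s, e in blocks[c]]
        if len(flat) < cfg.n_peaks_unaligned:
            raise SizingError("not enough lineage-specific blocks for unaligned peaks")
        pick = rng.choice(len(flat), cfg.n_peaks_unaligned, replace=False)
        for i, bi in enumerate(pick):
            chrom, s, e = flat[bi]
            mid = (s + e) // 2
            _write_motif(seqs[chrom], mid - w // 2, cons)
            name = f"pk_unal_{genome}_{i:04d}"
            rows[genome].append(_peak_row(chrom, mid, name, hw, rng.uniform(5, 50),
                                          rng.uniform(5, 50)))
            truth[name] = "unaligned"

    peaks_a = pd.DataFrame(rows["A"], columns=_PEAK_COLS)
    peaks_b = pd.DataFrame(rows["B"], columns=_PEAK_COLS)
    for df in (peaks_a, peaks_b):
        df.sort_values(["chrom", "start"], inplace=True, ignore_index=True)
    return peaks_a, peaks_b, truth


# ---------------------------------------------------------------------------
# reads


def simulate_reads(pair: AlleleGenomePair, peaks_a, peaks_b, cfg: SimConfig):
    """Draw ChIP-style reads around planted summits plus uniform background.

    Each peak contributes ``reads_per_peak`` reads whose midpoints fall
    within half a fragment of the summit, drawn from the allele carrying
    the peak; background reads are Poisson per kb from both alleles.
    Returns ``(reads, read_truth)``: a DataFrame (read_id, seq) and a
    truth DataFrame (read_id, allele, chrom, start) recording each
    read's allele and locus of origin.
    """
    rng = stage_rng(cfg.seed, "reads")
    half_frag = cfg.fragment_size // 2
    ids, seqs, truth = [], [], []

    def emit(genome, chrom, start, rid):
        L = pair.chrom_len(genome, chrom)
        start = int(np.clip(start, 0, L - cfg.read_len))
        truth.append((rid, genome, chrom, start))
        s = pair.seq(genome, chrom)[start:start + cfg.read_len]
        if cfg.read_error_rate > 0:
            arr = np.frombuffer(s.encode(), np.uint8).copy()
            hit = rng.random(arr.size) < cfg.read_error_rate
            n = int(hit.sum())
            if n:
                idx = np.searchsorted(_ASCII, arr[hit])
                arr[hit] = _ASCII[(idx + rng.integers(1, 4, n)) % 4]
            s = arr.tobytes().decode()
        if rng.random() < 0.5:
            s = revcomp(s)
        ids.append(rid)
        seqs.append(s)

    for genome, peaks in (("A", peaks_a), ("B", peaks_b)):
        for _, pk in peaks.iterrows():
            summit = int(pk.start + pk.summit)
            mids = rng.integers(summit - half_frag, summit + half_frag + 1,
                                cfg.reads_per_peak)
            for k, m in enumerate(mids):
                emit(genome, pk.chrom, int(m) - cfg.read_len // 2,
                     f"rd_{genome}_{pk['name']}_{k:03d}")

    for genome in ("A", "B"):
        for chrom in pair.chroms:
            L = pair.chrom_len(genome, chrom)
            n = rng.poisson(cfg.background_read_rate * L / 1000.0)
            for k, start in enumerate(rng.integers(0, L - cfg.read_len, n)):
                emit(genome, chrom, int(start), f"rd_{genome}_bg_{chrom}_{k:05d}")

    truth_df = pd.DataFrame(truth, columns=["read_id", "allele", "chrom", "start"])
    return pd.DataFrame({"read_id": ids, "seq": seqs}), truth_df


# ---------------------------------------------------------------------------
# expression


def _nb_draw(rng, mean, alpha):
    """Negative binomial with mean ``mean`` and var = mean + alpha*mean^2."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def simulate_expression(cfg: SimConfig):
    """Simulate per-allele counts before/after TF induction for homolog pairs.

    Each pair draws a regulation type from ``cfg.type_proportions``:
    type 0 no allele responds; 1 allele A only; 2 the two alleles shift in
    opposite directions; 3 allele B only; 4 both shift in the same
    direction.  Responsive alleles move by ``effect_size_log2`` in log2
    mean; counts are negative binomial.

    Returns ``(expr, gene_truth)``: a DataFrame with columns pair_id,
    gene_a, gene_b, a_ctrl, a_dox, b_ctrl, b_dox, and a DataFrame of the
    planted type and per-allele shift signs.
    """
    rng = stage_rng(cfg.seed, "expression")
    n = cfg.n_genes
    types = rng.choice(5, size=n, p=np.asarray(cfg.type_proportions))
    sign = rng.choice([-1, 1], size=n)
    sign_a = np.where(np.isin(types, [1, 2, 4]), sign, 0)
    sign_b = np.where(types == 3, sign, 0)
    sign_b = np.where(types == 4, sign, sign_b)
    sign_b = np.where(types == 2, -sign, sign_b)

    base = cfg.mean_expression
    eff = 2.0 ** (cfg.effect_size_log2)
    mean_a_dox = base * np.where(sign_a == 0, 1.0, eff ** sign_a)
    mean_b_dox = base * np.where(sign_b == 0, 1.0, eff ** sign_b)

    expr = pd.DataFrame({
        "pair_id": [f"pair_{i:05d}" for i in range(n)],
        "gene_a": [f"geneA_{i:05d}" for i in range(n)],
        "gene_b": [f"geneB_{i:05d}" for i in range(n)],
        "a_ctrl": _nb_draw(rng, np.full(n, base), cfg.dispersion),
        "a_dox": _nb_draw(rng, mean_a_dox, cfg.dispersion),
        "b_ctrl": _nb_draw(rng, np.full(n, base), cfg.dispersion),
        "b_dox": _nb_draw(rng, mean_b_dox, cfg.dispersion),
    })
    gene_truth = pd.DataFrame({
        "pair_id": expr.pair_id, "type": types,
        "sign_a": sign_a, "sign_b": sign_b,
    })
    return expr, gene_truth


def simulate_gene_anchors(pair: AlleleGenomePair, peaks, cfg: SimConfig,
                          offset: int = 10_000, genome: str = "A"):
    """Place gene TSSs a fixed offset from planted peak summits.

    A convenience for exercising peak-to-gene linkage on simulated data:
    each peak in ``peaks`` (one genome's coordinates) gets one gene whose
    TSS sits ``offset`` bp from the summit, strand alternating.  Returns
    a DataFrame (gene_id, chrom, tss, strand).
    """
    rng = stage_rng(cfg.seed, "genes")
    rows = []
    for i, (_, pk) in enumerate(peaks.iterrows()):
        summit = int(pk.start + pk.summit)
        strand = "+" if i % 2 == 0 else "-"
        shift = offset if rng.random() < 0.5 else -offset
        tss = max(0, min(summit + shift, pair.chrom_len(genome, pk.chrom) - 1))
        rows.append(dict(gene_id=f"g_{pk['name']}", chrom=pk.chrom,
                         tss=tss, strand=strand))
    return pd.DataFrame(rows)
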