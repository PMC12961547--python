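"""Pipeline orchestration and summary arithmetic.

``run_pipeline`` executes the full synthetic study end to end —
simulate the allodiploid genome pair, plant peaks, draw reads, assign
reads to alleles, count, project peaks both directions and classify
them, scan motifs, type homolog pairs by allele response, and link peaks
to genes — and returns a JSON-serialisable report including
truth-versus-recovered confusion tables.

The summary helpers reproduce the arithmetic behind printed headline
figures: class percentages with raw counts, differential-expression
up/down shares, and the conserved-regulation share among responsive
types.  Percentages round half-away-from-zero to one decimal (two
decimals below 1%).
"""

from __future__ import annotations

import json
import math
from importlib import resources

import numpy as np
import pandas as pd

from . import assign as assign_mod
from . import diffsignal, expression, linkage, motif, seqmap
from .config import SimConfig
from .simulate import (plant_peaks, simulate_expression, simulate_gene_anchors,
                       simulate_genome_pair, simulate_reads)


def round_pct(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of the printed figures."""
    f = 10 ** decimals
    return math.copysign(math.floor(abs(x) * f + 0.5) / f, x)


def class_percentages(counts) -> dict:
    """Percentages per orthology class from raw counts (1 decimal).

    ``counts`` maps class -> count; the total must be positive.  Returns
    {class: {"count": n, "pct": p}}.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    return {k: {"count": int(v), "pct": round_pct(100.0 * v / total)}
            for k, v in counts.items()}


def de_summary(n_up: int, n_down: int) -> dict:
    """Total and up/down percentage split of differential genes."""
    total = n_up + n_down
    if total == 0:
        return {"total": 0, "up_pct": None, "down_pct": None}
    return {"total": total,
            "up_pct": round_pct(100.0 * n_up / total),
            "down_pct": round_pct(100.0 * n_down / total)}


def type_summary(counts5) -> dict:
    """Total pairs and conserved-regulation share among responsive types.

    The share is type 4 over types 1-4 (pairs where at least one allele
    responded), to one decimal; undefined when no pair responded.
    """
    c = [int(x) for x in counts5]
    if len(c) != 5 or any(x < 0 for x in c):
        raise ValueError("need five non-negative type counts")
    responsive = sum(c[1:])
    share = round_pct(100.0 * c[4] / responsive) if responsive else None
    return {"total": sum(c), "conserved_share_pct": share}


def stronger_summary(n_a: int, n_b: int, total: int) -> dict:
    """Allele-stronger peak fractions of the full peak set (2 decimals)."""
    return {"a_stronger_pct": round_pct(100.0 * n_a / total, 2),
            "b_stronger_pct": round_pct(100.0 * n_b / total, 2)}


def default_pwm() -> motif.PWM:
    """The bundled synthetic caudal-type homeodomain-like test PWM."""
    text = (resources.files("cisdiv") / "data" / "caudal_like_synthetic.meme").read_text()
    return motif.PWM.from_meme(text)


def _confusion(truth: dict, predicted: dict, labels) -> dict:
    table = {t: {p: 0 for p in labels} for t in labels}
    for k, t in truth.items():
        p = predicted.get(k)
        if p in table[t]:
            table[t][p] += 1
    return table


def run_pipeline(cfg: SimConfig = None, outdir=None, pwm: motif.PWM = None,
                 seed_k: int = 12, motif_p: float = 1e-4) -> dict:
    """Run the synthetic study end to end; return the report dict.

    When ``outdir`` is given, genomes (FASTA), peaks (narrowPeak), and
    all stage tables (TSV) are written there along with report.json.
    Two runs with the same config produce identical reports.
    """
    from . import io

    cfg = cfg or SimConfig()
    pwm = pwm or default_pwm()
    report = {"seed": cfg.seed, "config": {"subst_rate": cfg.subst_rate,
                                           "n_genes": cfg.n_genes,
                                           "read_len": cfg.read_len}}

    pair = simulate_genome_pair(cfg)
    peaks_a, peaks_b, peak_truth = plant_peaks(pair, pwm, cfg)
    reads, read_truth_df = simulate_reads(pair, peaks_a, peaks_b, cfg)
    read_truth = dict(zip(read_truth_df.read_id, read_truth_df.allele))

    # --- allele assignment -------------------------------------------------
    seqs_a = {c: pair.seq("A", c) for c in pair.chroms}
    seqs_b = {c: pair.seq("B", c) for c in pair.chroms}
    idx_a = assign_mod.GenomeIndex(seqs_a, k=seed_k)
    idx_b = assign_mod.GenomeIndex(seqs_b, k=seed_k)
    assignments = assign_mod.assign_reads(reads, idx_a, idx_b,
                                          max_edit=cfg.read_len // 10)
    lab = assignments.label
    mapped = assignments[lab.isin(["A", "B"])]
    correct = sum(read_truth[r] == l for r, l in zip(mapped.read_id, mapped.label))
    report["read_assignment"] = {
        "n_reads": int(len(assignments)),
        "n_A": int((lab == "A").sum()), "n_B": int((lab == "B").sum()),
        "n_ambiguous": int((lab == "ambiguous").sum()),
        "n_unmapped": int((lab == "unmapped").sum()),
        "accuracy_pct": round_pct(100.0 * correct / max(len(mapped), 1)),
    }

    counts = assign_mod.count_matrix(assignments, peaks_a, peaks_b,
                                     pair.chroms, pair.chroms)

    # allele-stronger binding over conserved peak pairs
    ca = counts[counts.allele == "A"].set_index("name")["count"]
    cb = counts[counts.allele == "B"].set_index("name")["count"]
    pair_ids = [n[:-2] for n in peaks_a.name if n.startswith("pk_cons")]
    na = np.array([ca.get(p + "_A", 0) for p in pair_ids], dtype=float)
    nb = np.array([cb.get(p + "_B", 0) for p in pair_ids], dtype=float)
    stronger = diffsignal.classify_chip_stronger(na, nb)
    n_as = int((stronger == "A_stronger").sum())
    n_bs = int((stronger == "B_stronger").sum())
    report["binding_strength"] = dict(
        n_pairs=len(pair_ids), n_a_stronger=n_as, n_b_stronger=n_bs,
        **stronger_summary(n_as, n_bs, max(len(pair_ids), 1)))

    # --- peak projection, both directions ----------------------------------
    proj = {}
    for direction, (src_peaks, src_seqs, tgt_seqs, tgt_peaks) in {
            "A_to_B": (peaks_a, seqs_a, seqs_b, peaks_b),
            "B_to_A": (peaks_b, seqs_b, seqs_a, peaks_a)}.items():
        index = seqmap.TargetIndex(tgt_seqs)
        pr = seqmap.project_peaks(src_peaks, src_seqs, index, tgt_peaks,
                                  window_halfwidth=cfg.window_halfwidth)
        proj[direction] = pr
        cc = seqmap.class_counts(pr)
        classified = {k: int(cc[k]) for k in ("conserved", "loss", "unaligned")}
        report.setdefault("peak_classes", {})[direction] = {
            "counts": classified,
            "multi_mapped": int(cc["multi_mapped"]),
            "percentages": {k: v["pct"]
                            for k, v in class_percentages(classified).items()},
            "confusion": _confusion(
                {n: peak_truth[n] for n in pr.name},
                dict(zip(pr.name, pr.klass)),
                ("conserved", "loss", "unaligned")),
        }

    # --- motif occurrence by class (A -> B direction) ----------------------
    windows = {pk["name"]: seqmap.extract_window(pk, seqs_a,
                                                 cfg.window_halfwidth)[0]
               for _, pk in peaks_a.iterrows()}
    klass_by_peak = {n: k for n, k in zip(proj["A_to_B"].name,
                                          proj["A_to_B"].klass)
                     if k in ("conserved", "loss", "unaligned")}
    frac = motif.motif_fraction_by_class(windows, klass_by_peak, pwm, motif_p)
    report["motif_fraction"] = {k: round(float(v), 4) for k, v in frac.items()}

    # --- expression typing -------------------------------------------------
    expr, gene_truth = simulate_expression(cfg)
    typed = expression.type_genes(expr)
    tc = expression.type_counts(typed)
    truth_types = dict(zip(gene_truth.pair_id, gene_truth.type.astype(int)))
    pred_types = dict(zip(typed.pair_id, typed.type.astype(int)))
    report["gene_types"] = {
        "counts": {int(k): int(v) for k, v in tc.items()},
        "proportions_pct": {int(k): round_pct(100.0 * v / tc.sum())
                            for k, v in tc.items()},
        "confusion": _confusion(truth_types, pred_types, tuple(range(5))),
        **type_summary(tc.to_numpy()),
    }

    # --- peak-gene linkage -------------------------------------------------
    genes = simulate_gene_anchors(pair, peaks_a, cfg)
    pk_link = peaks_a.merge(proj["A_to_B"][["name", "klass"]], on="name")
    links = linkage.link(genes, pk_link,
                         chrom_lengths={c: pair.chrom_len("A", c)
                                        for c in pair.chroms})
    # round-robin demo types over linked genes so the composition table
    # is exercised even though anchors are synthetic
    gene_types = pd.DataFrame({
        "gene_id": genes.gene_id,
        "type": [t for t, _ in zip([0, 1, 3, 4] * len(genes), genes.gene_id)]})
    comp = linkage.class_composition_by_type(links, gene_types)
    report["linked_peaks"] = {"n_links": int(len(links))}
    report["class_composition_by_type"] = {
        str(t): ({k: round(float(v), 4) for k, v in row.items()}
                 if not row.isna().any() else None)
        for t, row in comp.iterrows()}

    if outdir is not None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pair.genomes_fasta(out / "genome_A.fa", out / "genome_B.fa")
        io.write_narrowpeak(out / "peaks_A.narrowPeak", peaks_a)
        io.write_narrowpeak(out / "peaks_B.narrowPeak", peaks_b)
        io.write_tsv(out / "assignments.tsv", assignments)
        io.write_tsv(out / "counts.tsv", counts)
        io.write_tsv(out / "projection_A_to_B.tsv", proj["A_to_B"])
        io.write_tsv(out / "projection_B_to_A.tsv", proj["B_to_A"])
        io.write_tsv(out / "typed_genes.tsv", typed)
        io.write_tsv(out / "links.tsv", links)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
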