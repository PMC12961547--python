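#!/usr/bin/env python
"""Simulate the synthetic allodiploid study and write every input table.

Generates the two parental genomes at 5% substitution divergence with
lineage-specific blocks, plants 100 binding peaks per orthology class,
draws ChIP-style reads around the planted summits, and simulates
per-allele expression responses for 2,000 homolog pairs.  Everything
downstream (02-07) starts from the files written here.
"""

from pathlib import Path

from cisdiv import SimConfig, io, report, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    pwm = report.default_pwm()

    pair = simulate.simulate_genome_pair(cfg)
    peaks_a, peaks_b, peak_truth = simulate.plant_peaks(pair, pwm, cfg)
    # written after planting: the FASTA genomes carry the embedded motifs
    pair.genomes_fasta(OUT / "genome_A.fa", OUT / "genome_B.fa")
    io.write_narrowpeak(OUT / "peaks_A.narrowPeak", peaks_a)
    io.write_narrowpeak(OUT / "peaks_B.narrowPeak", peaks_b)
    io.write_tsv(OUT / "peak_truth.tsv",
                 __import__("pandas").DataFrame(
                     sorted(peak_truth.items()), columns=["name", "klass"]))

    reads, read_truth = simulate.simulate_reads(pair, peaks_a, peaks_b, cfg)
    io.write_fasta(OUT / "reads.fa", dict(zip(reads.read_id, reads.seq)))
    io.write_tsv(OUT / "read_truth.tsv", read_truth)

    expr, gene_truth = simulate.simulate_expression(cfg)
    io.write_tsv(OUT / "expression.tsv", expr)
    io.write_tsv(OUT / "gene_truth.tsv", gene_truth)

    genes = simulate.simulate_gene_anchors(pair, peaks_a, cfg)
    io.write_tsv(OUT / "genes.tsv", genes)

    print(f"genomes: {sum(pair.chrom_len('A', c) for c in pair.chroms):,} bp (A), "
          f"{sum(pair.chrom_len('B', c) for c in pair.chroms):,} bp (B)")
    print(f"planted peaks: {len(peaks_a)} per genome "
          f"({cfg.n_peaks_conserved} conserved / {cfg.n_peaks_loss} loss / "
          f"{cfg.n_peaks_unaligned} unaligned)")
    print(f"reads: {len(reads):,}; homolog pairs: {len(expr):,}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
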