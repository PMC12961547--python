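#!/usr/bin/env python
"""Scan peak windows for the TF motif and tabulate occurrence by class.

Uses the bundled synthetic caudal-type homeodomain-like PWM to scan the
400 bp summit window of every genome-A peak and reports the fraction of
peaks with at least one hit (p <= 1e-4) in each orthology class from
03_project_peaks.py.
"""

from pathlib import Path

from cisdiv import io, motif, report, seqmap

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
PROJ = SIM.parent / "projection"
OUT = SIM.parent / "motif"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    pwm = report.default_pwm()
    seqs_a = io.read_fasta(SIM / "genome_A.fa")
    peaks_a = io.read_narrowpeak(SIM / "peaks_A.narrowPeak")
    pr = io.read_tsv(PROJ / "projection_A_to_B.tsv")

    windows = {pk["name"]: seqmap.extract_window(pk, seqs_a)[0]
               for _, pk in peaks_a.iterrows()}
    klass = {n: k for n, k in zip(pr.name, pr.klass)
             if k in ("conserved", "loss", "unaligned")}
    frac = motif.motif_fraction_by_class(windows, klass, pwm)
    frac.rename_axis("klass").reset_index().to_csv(
        OUT / "motif_fraction_by_class.tsv", sep="\t", index=False)
    print(f"PWM {pwm.name} (width {pwm.width}, consensus {pwm.consensus})")
    for k, v in frac.items():
        print(f"  {k}: {100 * v:.1f}% of peaks carry a motif hit")


if __name__ == "__main__":
    main()
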