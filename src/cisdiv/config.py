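"""Simulation configuration for the synthetic allodiploid dataset.

The simulator emulates an allodiploid cell line carrying two complete
haploid genomes from related species (allele A, mouse-like; allele B,
rat-like).  A single :class:`SimConfig` fixes every stochastic choice:
the divergence between the two alleles, how many TF-binding peaks are
planted in each cross-genome orthology class, how ChIP-style reads are
drawn around peak summits, and how per-allele expression responds to TF
induction.  Identical configs (including the seed) produce byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Paper-scale five-way split of homolog pairs by allele response
#: (no change / A-only / opposite / B-only / concordant), normalised.
DEFAULT_TYPE_PROPORTIONS = (
    5592 / 7372,
    496 / 7372,
    1 / 7372,
    425 / 7372,
    858 / 7372,
)


class SizingError(ValueError):
    """Requested peaks/blocks cannot fit in the configured genome."""


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic allodiploid data generator.

    Rates are per site, lengths in bp.  ``type_proportions`` orders the
    five regulation types 0..4 and must sum to 1.
    """

    seed: int = 0

    # genome pair
    n_chrom_per_genome: int = 2
    chrom_length: int = 500_000
    subst_rate: float = 0.05
    indel_rate: float = 0.002
    mean_indel_len: float = 3.0
    n_unalignable_blocks: int = 100  # lineage-specific insertions per genome

    # peaks
    n_peaks_conserved: int = 100
    n_peaks_loss: int = 100
    n_peaks_unaligned: int = 100
    peak_halfwidth: int = 150      # emitted peak interval = summit +/- halfwidth
    window_halfwidth: int = 200    # projection window = summit +/- 200 (400 bp)
    loss_extra_mut_rate: float = 0.0   # extra local mutation of the unbound homolog window
    loss_motif_ablation: float = 0.0   # fraction of loss peaks planted without the consensus

    # reads
    reads_per_peak: int = 50
    read_len: int = 100
    fragment_size: int = 250       # ChIP fragment span around the summit
    background_read_rate: float = 0.05  # reads per kb per allele
    read_error_rate: float = 0.0

    # expression
    n_genes: int = 2000
    type_proportions: tuple = DEFAULT_TYPE_PROPORTIONS
    effect_size_log2: float = 3.0
    dispersion: float = 0.05       # NB overdispersion alpha; var = m + alpha m^2
    mean_expression: float = 500.0

    def __post_init__(self):
        for name in ("subst_rate", "indel_rate", "background_read_rate",
                     "read_error_rate", "loss_extra_mut_rate", "loss_motif_ablation"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0) and name != "background_read_rate":
                raise ValueError(f"{name}={v} must be in [0, 1)")
        if abs(sum(self.type_proportions) - 1.0) > 1e-9:
            raise ValueError("type_proportions must sum to 1 +/- 1e-9")
        if len(self.type_proportions) != 5:
            raise ValueError("type_proportions must have 5 entries")
        for name in ("n_peaks_conserved", "n_peaks_loss", "n_peaks_unaligned"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_len > self.chrom_length:
            raise ValueError("read_len exceeds chrom_length")
        # rough occupancy check: planted windows and blocks must fit with room
        # to spare for rejection sampling of non-overlapping placements
        window = 2 * self.window_halfwidth
        per_genome_bp = self.n_chrom_per_genome * self.chrom_length
        need = (3 * window * (self.n_peaks_conserved + 2 * self.n_peaks_loss)
                + self.n_unalignable_blocks * self.block_length)
        if need > 0.5 * per_genome_bp:
            raise SizingError(
                f"genome too small: ~{need} bp of planted features requested in "
                f"{per_genome_bp} bp per genome (must be under half)")
        if self.n_peaks_unaligned > self.n_unalignable_blocks:
            raise SizingError(
                "n_peaks_unaligned exceeds n_unalignable_blocks; each unaligned "
                "peak needs its own lineage-specific block")

    @property
    def block_length(self) -> int:
        # 3x the projection window guarantees non-alignability at 70% identity
        return 6 * self.window_halfwidth

    def with_(self, **kw) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


# fixed stage ids so each pipeline stage gets an independent, reproducible
# RNG sub-stream derived from the one global seed
_STAGES = {"genome": 1, "peaks": 2, "reads": 3, "expression": 4, "genes": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG sub-stream keyed by the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))
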