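"""Generator correctness: divergence calibration, truth bookkeeping,
determinism, and sizing errors."""

import numpy as np
import pandas as pd
import pytest

from cisdiv import SimConfig, SizingError
from cisdiv import motif, simulate


def small_cfg(**kw):
    base = dict(seed=7, n_chrom_per_genome=1, chrom_length=120_000,
                n_peaks_conserved=10, n_peaks_loss=10, n_peaks_unaligned=5,
                n_unalignable_blocks=5, reads_per_peak=5,
                background_read_rate=0.0, n_genes=200)
    base.update(kw)
    return SimConfig(**base)


def identical_cfg(**kw):
    return small_cfg(subst_rate=0.0, indel_rate=0.0, n_unalignable_blocks=0,
                     n_peaks_unaligned=0, **kw)


class TestGenomePair:
    def test_zero_divergence_gives_identical_genomes_and_identity_map(self):
        pair = simulate.simulate_genome_pair(identical_cfg())
        for c in pair.chroms:
            assert pair.seq("A", c) == pair.seq("B", c)
            a_pos, b_pos = pair.coord_map[c]
            assert np.array_equal(a_pos, b_pos)
            assert a_pos.size == pair.chrom_len("A", c)

    def test_realised_mismatch_fraction_matches_substitution_rate(self):
        cfg = SimConfig(seed=11, n_chrom_per_genome=1, chrom_length=100_000,
                        subst_rate=0.05, n_unalignable_blocks=10,
                        n_peaks_conserved=5, n_peaks_loss=5, n_peaks_unaligned=5)
        pair = simulate.simulate_genome_pair(cfg)
        a_pos, b_pos = pair.coord_map["chr1"]
        mism = (pair.a["chr1"][a_pos] != pair.b["chr1"][b_pos]).mean()
        se = np.sqrt(0.05 * 0.95 / a_pos.size)
        assert abs(mism - 0.05) <= 3 * se

    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        cfg = small_cfg()
        for run in ("x", "y"):
            pair = simulate.simulate_genome_pair(cfg)
            pair.genomes_fasta(tmp_path / f"{run}_A.fa", tmp_path / f"{run}_B.fa")
        for g in ("A", "B"):
            assert ((tmp_path / f"x_{g}.fa").read_bytes()
                    == (tmp_path / f"y_{g}.fa").read_bytes())

    def test_coordinate_map_round_trip(self):
        pair = simulate.simulate_genome_pair(small_cfg())
        a_pos, _ = pair.coord_map["chr1"]
        for pos in a_pos[:: max(1, a_pos.size // 500)]:
            b = pair.map_pos("chr1", int(pos), "A")
            assert b is not None
            assert pair.map_pos("chr1", b, "B") == int(pos)

    def test_map_strictly_increasing(self):
        pair = simulate.simulate_genome_pair(small_cfg())
        for c in pair.chroms:
            a_pos, b_pos = pair.coord_map[c]
            assert (np.diff(a_pos) > 0).all()
            assert (np.diff(b_pos) > 0).all()

    def test_sizing_error_for_tiny_chromosome(self):
        with pytest.raises(SizingError):
            SimConfig(seed=0, chrom_length=5_000)


class TestPlantPeaks:
    def test_class_counts_exactly_match_config(self, sim, cfg):
        counts = pd.Series(sim["peak_truth"]).value_counts()
        # conserved pairs appear once per genome; loss/unaligned planted per genome
        assert counts["conserved"] == 2 * cfg.n_peaks_conserved
        assert counts["loss"] == 2 * cfg.n_peaks_loss
        assert counts["unaligned"] == 2 * cfg.n_peaks_unaligned

    def test_conserved_summits_map_to_a_peak_in_the_other_genome(self, sim):
        peaks_b = sim["peaks_b"].copy()
        peaks_b["summit_abs"] = peaks_b.start + peaks_b.summit
        by_name = dict(zip(peaks_b.name, peaks_b.summit_abs))
        pa = sim["peaks_a"]
        for _, pk in pa[pa.name.str.startswith("pk_cons")].iterrows():
            mate = pk["name"][:-2] + "_B"
            mapped = sim["pair"].map_pos(pk.chrom, int(pk.start + pk.summit), "A")
            assert mapped is not None
            assert abs(mapped - by_name[mate]) <= 2

    def test_unaligned_summits_fall_inside_lineage_blocks(self, sim):
        pair = sim["pair"]
        for genome, peaks in (("A", sim["peaks_a"]), ("B", sim["peaks_b"])):
            blocks = pair.blocks_a if genome == "A" else pair.blocks_b
            sub = peaks[peaks.name.str.startswith(f"pk_unal_{genome}")]
            assert len(sub) > 0
            for _, pk in sub.iterrows():
                summit = int(pk.start + pk.summit)
                assert any(s <= summit < e for s, e in blocks[pk.chrom])
                # and the summit position is absent from the homology map
                assert pair.map_pos(pk.chrom, summit, genome) is None

    def test_scanner_finds_planted_consensus_in_every_peak(self, sim, pwm):
        from cisdiv import seqmap
        for _, pk in sim["peaks_a"].head(30).iterrows():
            window, _ = seqmap.extract_window(pk, sim["seqs_a"])
            assert motif.has_hit(window, pwm)


class TestReads:
    def test_read_count_is_peaks_times_reads_per_peak_without_background(self):
        cfg = small_cfg()
        pair = simulate.simulate_genome_pair(cfg)
        pwm = motif.PWM(np.full((8, 4), 0.25))
        pa, pb, _ = simulate.plant_peaks(pair, pwm, cfg)
        reads, truth = simulate.simulate_reads(pair, pa, pb, cfg)
        assert len(reads) == cfg.reads_per_peak * (len(pa) + len(pb))
        assert len(truth) == len(reads)
        assert set(truth.allele) == {"A", "B"}

    def test_reads_originate_near_planted_summits(self):
        cfg = small_cfg()
        pair = simulate.simulate_genome_pair(cfg)
        pwm = motif.PWM(np.full((8, 4), 0.25))
        pa, pb, _ = simulate.plant_peaks(pair, pwm, cfg)
        _, truth = simulate.simulate_reads(pair, pa, pb, cfg)
        summits = {g: {} for g in "AB"}
        for g, peaks in (("A", pa), ("B", pb)):
            for _, pk in peaks.iterrows():
                summits[g].setdefault(pk.chrom, []).append(int(pk.start + pk.summit))
        max_d = cfg.fragment_size // 2 + cfg.read_len
        for _, rd in truth.iterrows():
            mid = rd.start + cfg.read_len // 2
            assert min(abs(mid - s) for s in summits[rd.allele][rd.chrom]) <= max_d

    def test_most_reads_cover_a_diagnostic_site(self, sim, cfg):
        """Reads should overlap alleles-distinguishing positions; homologous
        columns that differ and lineage-specific positions both count."""
        rcfg = cfg.with_(reads_per_peak=10, background_read_rate=0.0)
        pair = sim["pair"]
        _, truth = simulate.simulate_reads(pair, sim["peaks_a"], sim["peaks_b"], rcfg)
        diag = {}
        for g in "AB":
            for c in pair.chroms:
                a_pos, b_pos = pair.coord_map[c]
                differ = pair.a[c][a_pos] != pair.b[c][b_pos]
                pos = a_pos if g == "A" else b_pos
                # mark homologous-but-different and unmapped (lineage) sites
                mask = np.ones(pair.chrom_len(g, c), dtype=bool)
                mask[pos] = False          # mapped sites default non-diagnostic
                mask[pos[differ]] = True   # unless the column differs
                diag[(g, c)] = np.cumsum(mask)
        covered = 0
        for _, rd in truth.iterrows():
            cs = diag[(rd.allele, rd.chrom)]
            lo = cs[rd.start - 1] if rd.start > 0 else 0
            covered += cs[rd.start + rcfg.read_len - 1] - lo > 0
        assert covered / len(truth) >= 0.95


class TestExpression:
    def test_pure_null_proportions_plant_only_type_zero(self):
        cfg = small_cfg(type_proportions=(1.0, 0, 0, 0, 0))
        _, truth = simulate.simulate_expression(cfg)
        assert (truth.type == 0).all()
        assert (truth.sign_a == 0).all() and (truth.sign_b == 0).all()

    def test_opposite_type_plants_strictly_opposite_signs(self):
        cfg = small_cfg(type_proportions=(0, 0, 1.0, 0, 0))
        _, truth = simulate.simulate_expression(cfg)
        assert (truth.sign_a * truth.sign_b == -1).all()

    def test_concordant_type_plants_equal_signs(self):
        cfg = small_cfg(type_proportions=(0, 0, 0, 0, 1.0))
        _, truth = simulate.simulate_expression(cfg)
        assert (truth.sign_a == truth.sign_b).all()
        assert (truth.sign_a != 0).all()

    def test_counts_are_reproducible_and_scaled_by_effect(self):
        cfg = small_cfg(type_proportions=(0, 1.0, 0, 0, 0), dispersion=0.0,
                        effect_size_log2=3.0, mean_expression=1000.0)
        e1, t1 = simulate.simulate_expression(cfg)
        e2, _ = simulate.simulate_expression(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        up = t1.sign_a == 1
        ratio = (e1.a_dox[up] + 1) / (e1.a_ctrl[up] + 1)
        assert abs(np.log2(ratio).mean() - 3.0) < 0.3

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(type_proportions=(0.76, 0.07, 0.0001, 0.06, 0.12))
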