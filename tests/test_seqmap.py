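"""Peak projection: window arithmetic, the seeded aligner against a DP
oracle, filtering and classification rules, and planted-class recovery."""

import edlib
import numpy as np
import pandas as pd
import pytest

from cisdiv import SimConfig, seqmap, simulate
from cisdiv.simulate import revcomp


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(seq, rate, seed):
    rng = np.random.default_rng(seed)
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = "ACGT"[(("ACGT".index(out[i])) + rng.integers(1, 4)) % 4]
    return "".join(out)


def edlib_identity(query, target):
    """Independent global-alignment identity oracle (percent)."""
    res = edlib.align(query, target, mode="NW", task="path")
    eq = x = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            if ch == "=":
                eq += int(num)
            elif ch == "X":
                x += int(num)
            num = ""
    return 100.0 * eq / (eq + x)


class TestExtractWindow:
    def peak(self, start, summit_off):
        return {"chrom": "chr1", "start": start, "summit": summit_off}

    def test_window_is_400bp_half_open_around_summit(self):
        genome = {"chr1": random_seq(10_000, 0)}
        seq, clipped = seqmap.extract_window(self.peak(450, 50), genome)
        assert seq == genome["chr1"][300:700]
        assert not clipped

    def test_window_near_chromosome_start_is_clipped_and_flagged(self):
        genome = {"chr1": random_seq(10_000, 0)}
        seq, clipped = seqmap.extract_window(self.peak(50, 50), genome)
        assert seq == genome["chr1"][0:300]
        assert clipped

    def test_summit_outside_chromosome_raises(self):
        with pytest.raises(ValueError):
            seqmap.extract_window(self.peak(9_990, 50), {"chr1": random_seq(10_000, 0)})


@pytest.fixture(scope="module")
def target():
    seqs = {"chrT": random_seq(50_000, 3)}
    return seqs, seqmap.TargetIndex(seqs)


class TestSeededAligner:
    def test_exact_substring_aligns_perfectly(self, target):
        seqs, index = target
        q = seqs["chrT"][20_000:20_400]
        hits = seqmap.seeded_align(q, index)
        assert hits
        h = hits[0]
        assert (h.t_start, h.t_end) == (20_000, 20_400)
        assert h.identity == 100.0 and h.score == 400
        assert h.aligned_fraction == 1.0 and h.strand == "+"

    def test_reverse_complement_query_hits_minus_strand(self, target):
        seqs, index = target
        q = revcomp(seqs["chrT"][20_000:20_400])
        h = seqmap.seeded_align(q, index)[0]
        assert (h.t_start, h.t_end, h.strand) == (20_000, 20_400, "-")
        assert h.score == 400

    def test_short_query_rejected(self, target):
        with pytest.raises(ValueError):
            seqmap.seeded_align("ACGT" * 10, target[1])

    def test_random_query_finds_nothing(self, target):
        assert seqmap.seeded_align(random_seq(400, 77), target[1]) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_identity_close_to_global_dp_oracle(self, target, seed):
        """On a diverged homologous pair, the seeded aligner's identity
        must sit within 2 points of a full global-DP alignment."""
        seqs, index = target
        start = 1000 + 5000 * seed
        span = seqs["chrT"][start:start + 400]
        q = mutate(span, 0.05, seed)
        h = seqmap.seeded_align(q, index)[0]
        assert abs(h.identity - edlib_identity(q, span)) <= 2.0


class TestBestHitFilter:
    def hit(self, score, frac=1.0, chrom="c", t=0):
        m = score  # all-match hit of the given score
        return seqmap.MapHit(chrom, "+", t, t + m, 0, int(400 * frac),
                             m, 0, 0, 0, 400)

    def test_single_qualifying_hit(self):
        status, best = seqmap.best_hit_filter([self.hit(300)])
        assert status == "single_hit" and best.score == 300

    def test_low_coverage_hits_drop_to_no_hit(self):
        status, best = seqmap.best_hit_filter([self.hit(300, frac=0.5)])
        assert status == "no_hit" and best is None

    def test_equal_scores_are_multi_mapped_at_any_ratio(self):
        for ratio in (0.5, 0.95, 1.0):
            status, _ = seqmap.best_hit_filter(
                [self.hit(300), self.hit(300, t=10_000)], single_hit_ratio=ratio)
            assert status == "multi_mapped"

    def test_clear_best_hit_survives_near_tie_rule(self):
        status, best = seqmap.best_hit_filter(
            [self.hit(300), self.hit(200, t=10_000)], single_hit_ratio=0.95)
        assert status == "single_hit" and best.score == 300


class TestClassification:
    def target_peaks(self):
        return pd.DataFrame({"chrom": ["c"], "start": [1000], "end": [1400],
                             "name": ["tp"]})

    def hit(self, t_start, t_end):
        m = t_end - t_start
        return seqmap.MapHit("c", "+", t_start, t_end, 0, 400, m, 0, 0, 0, 400)

    def test_no_hit_is_unaligned(self):
        assert seqmap.classify_peak("no_hit", None, self.target_peaks()) == "unaligned"

    def test_full_coverage_is_conserved(self):
        k = seqmap.classify_peak("single_hit", self.hit(1000, 1400),
                                 self.target_peaks())
        assert k == "conserved"

    def test_exactly_half_coverage_is_loss(self):
        # overlap 200 of a 400 bp peak: strictly-more-than-half rule
        k = seqmap.classify_peak("single_hit", self.hit(1200, 1600),
                                 self.target_peaks())
        assert k == "loss"
        k = seqmap.classify_peak("single_hit", self.hit(1199, 1600),
                                 self.target_peaks())
        assert k == "conserved"

    def test_multi_mapped_is_excluded(self):
        assert seqmap.classify_peak("multi_mapped", None, self.target_peaks()) is None


class TestMatchedBases:
    def test_identical_window_gives_full_length(self):
        h = seqmap.MapHit("c", "+", 0, 400, 0, 400, 400, 0, 0, 0, 400)
        assert seqmap.matched_bases("single_hit", h) == 400

    def test_no_hit_gives_zero(self):
        assert seqmap.matched_bases("no_hit", None) == 0


class TestOnSimulation:
    def test_classes_partition_all_projected_peaks(self, projections):
        for pr in projections.values():
            cc = seqmap.class_counts(pr)
            assert cc.sum() == len(pr)

    def test_planted_classes_recovered_both_directions(self, projections, sim, cfg):
        for direction in ("A_to_B", "B_to_A"):
            pr = projections[direction]
            truth = pd.Series({n: sim["peak_truth"][n] for n in pr.name})
            cc = seqmap.class_counts(pr)
            for klass, planted in (("conserved", cfg.n_peaks_conserved),
                                   ("loss", cfg.n_peaks_loss),
                                   ("unaligned", cfg.n_peaks_unaligned)):
                assert abs(int(cc[klass]) - planted) <= 5
            agree = (truth == pr.set_index("name").klass).mean()
            assert agree >= 0.95

    def test_identical_genomes_give_all_conserved_both_ways(self):
        from test_simulate import identical_cfg
        from cisdiv.motif import PWM
        cfg = identical_cfg(n_peaks_loss=0)
        pair = simulate.simulate_genome_pair(cfg)
        pwm = PWM(np.eye(4)[[0, 1, 2, 3, 0, 1, 2, 3]])
        pa, pb, _ = simulate.plant_peaks(pair, pwm, cfg)
        seqs = {c: pair.seq("A", c) for c in pair.chroms}
        index = seqmap.TargetIndex(seqs)
        for src, tgt in ((pa, pb), (pb, pa)):
            pr = seqmap.project_peaks(src, seqs, index, tgt)
            assert (pr.klass == "conserved").all()

    def test_raising_min_identity_never_increases_conserved(self, sim):
        index = seqmap.TargetIndex(sim["seqs_b"])
        sub = sim["peaks_a"].iloc[:40]
        prev = None
        for min_id in (70.0, 85.0, 95.0):
            pr = seqmap.project_peaks(sub, sim["seqs_a"], index, sim["peaks_b"],
                                      min_identity=min_id)
            n = int((pr.klass == "conserved").sum())
            if prev is not None:
                assert n <= prev
            prev = n

    def test_loss_windows_with_extra_mutations_match_fewer_bases(self, pwm):
        cfg = SimConfig(seed=5, n_chrom_per_genome=1, chrom_length=200_000,
                        n_peaks_conserved=25, n_peaks_loss=25,
                        n_peaks_unaligned=0, n_unalignable_blocks=0,
                        loss_extra_mut_rate=0.12)
        pair = simulate.simulate_genome_pair(cfg)
        pa, pb, truth = simulate.plant_peaks(pair, pwm, cfg)
        index = seqmap.TargetIndex({c: pair.seq("B", c) for c in pair.chroms})
        pr = seqmap.project_peaks(pa, {c: pair.seq("A", c) for c in pair.chroms},
                                  index, pb)
        klass = pr.set_index("name")
        mb = {k: klass.matched_bases[[n for n in klass.index
                                      if truth[n] == k]].mean()
              for k in ("conserved", "loss")}
        assert mb["conserved"] > mb["loss"]
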