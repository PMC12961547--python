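"""Shared fixtures: one moderately sized simulation reused across tests.

The session-scoped bundle runs the expensive stages (genome pair, peak
planting, projection in both directions) once; tests that need different
generator settings build their own small configs.
"""

import numpy as np
import pytest

from cisdiv import SimConfig
from cisdiv import assign as assign_mod
from cisdiv import seqmap, simulate
from cisdiv.report import default_pwm

SEED = 20260926


@pytest.fixture(scope="session")
def pwm():
    return default_pwm()


@pytest.fixture(scope="session")
def cfg():
    return SimConfig(seed=SEED)


@pytest.fixture(scope="session")
def sim(cfg, pwm):
    """Genome pair with planted peaks (default study conditions)."""
    pair = simulate.simulate_genome_pair(cfg)
    peaks_a, peaks_b, peak_truth = simulate.plant_peaks(pair, pwm, cfg)
    return dict(pair=pair, peaks_a=peaks_a, peaks_b=peaks_b,
                peak_truth=peak_truth,
                seqs_a={c: pair.seq("A", c) for c in pair.chroms},
                seqs_b={c: pair.seq("B", c) for c in pair.chroms})


@pytest.fixture(scope="session")
def projections(sim, cfg):
    """Peak projections in both directions on the shared simulation."""
    out = {}
    for direction, (pk, src, tgt, tpk) in {
            "A_to_B": (sim["peaks_a"], sim["seqs_a"], sim["seqs_b"], sim["peaks_b"]),
            "B_to_A": (sim["peaks_b"], sim["seqs_b"], sim["seqs_a"], sim["peaks_a"])}.items():
        index = seqmap.TargetIndex(tgt)
        out[direction] = seqmap.project_peaks(pk, src, index, tpk,
                                              window_halfwidth=cfg.window_halfwidth)
    return out


@pytest.fixture(scope="session")
def assignment_run(sim, cfg):
    """Roughly ten thousand error-free reads assigned to both alleles."""
    rcfg = cfg.with_(reads_per_peak=17, background_read_rate=0.0)
    reads, truth = simulate.simulate_reads(sim["pair"], sim["peaks_a"],
                                           sim["peaks_b"], rcfg)
    idx_a = assign_mod.GenomeIndex(sim["seqs_a"])
    idx_b = assign_mod.GenomeIndex(sim["seqs_b"])
    asg = assign_mod.assign_reads(reads, idx_a, idx_b,
                                  max_edit=rcfg.read_len // 10)
    return dict(reads=reads, truth=truth, assignments=asg,
                idx_a=idx_a, idx_b=idx_b)


def native_semiglobal_min_edit(read: str, genome: str) -> int:
    """Independent DP oracle: min Levenshtein distance of ``read`` against
    any substring of ``genome`` (free start/end in the genome)."""
    r = np.frombuffer(read.encode(), np.uint8)
    g = np.frombuffer(genome.encode(), np.uint8)
    pos = np.arange(g.size + 1, dtype=np.int32)
    prev = np.zeros(g.size + 1, dtype=np.int32)  # free leading gap in genome
    for i in range(1, r.size + 1):
        cur = np.empty(g.size + 1, dtype=np.int32)
        cur[0] = i
        cur[1:] = np.minimum(prev[:-1] + (g != r[i - 1]), prev[1:] + 1)
        # consume-genome transitions: cur[j] = min_{k<=j} cur[k] + (j - k)
        t = cur - pos
        np.minimum.accumulate(t, out=t)
        cur = np.minimum(cur, t + pos)
        prev = cur
    return int(prev.min())
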