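import math

import numpy as np
import pytest
from scipy import stats

from methfoot import dmr_detection as dd
from methfoot import synthetic_data as sd
from methfoot.types import Accession, Context, Population

from conftest import make_methylome, reciprocal_overlap


def _group(positions, levels_by_acc, depth=20, prefix="a"):
    """Methylomes with exact per-site levels (counts = level * depth)."""
    out = []
    for i, levels in enumerate(levels_by_acc):
        n_meth = np.round(np.asarray(levels) * depth).astype(int)
        out.append(make_methylome(positions, n_meth, depth - n_meth, accession=f"{prefix}{i}"))
    return out


# ---------------------------------------------------------------------------
# candidate blocks
# ---------------------------------------------------------------------------


def test_blocks_require_gaps_strictly_under_300_and_eight_sites():
    flat = lambda n: [[0.1] * n] * 3
    pos8 = np.arange(8) * 100
    blocks = dd.build_candidate_blocks(
        _group(pos8, flat(8)), _group(pos8, flat(8), prefix="b"),
        "Chr1", "CG", min_accessions_per_group=2,
    )
    assert len(blocks) == 1 and blocks[0].n_sites == 8

    # one gap of exactly 300 bp splits the run; both halves < 8 sites
    pos_split = np.array([0, 100, 200, 300, 600, 700, 800, 900])
    assert dd.build_candidate_blocks(
        _group(pos_split, flat(8)), _group(pos_split, flat(8), prefix="b"),
        "Chr1", "CG", min_accessions_per_group=2,
    ) == []

    # seven sites never form a block
    pos7 = np.arange(7) * 100
    assert dd.build_candidate_blocks(
        _group(pos7, flat(7)), _group(pos7, flat(7), prefix="b"),
        "Chr1", "CG", min_accessions_per_group=2,
    ) == []


def test_blocks_drop_sites_without_enough_covered_accessions():
    pos = np.arange(10) * 50
    a = _group(pos, [[0.2] * 10] * 3)
    # zero depth at one site for every group-B accession -> site trimmed
    b = []
    for i in range(3):
        n_meth = np.full(10, 4)
        n_unmeth = np.full(10, 16)
        n_meth[4] = 0
        n_unmeth[4] = 0
        b.append(make_methylome(pos, n_meth, n_unmeth, accession=f"b{i}"))
    blocks = dd.build_candidate_blocks(a, b, "Chr1", "CG", min_accessions_per_group=2)
    assert len(blocks) == 1 and blocks[0].n_sites == 9
    assert 200 not in blocks[0].positions


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _block_from_d(d):
    """A CandidateBlock whose group-mean difference equals d exactly."""
    n = len(d)
    pos = np.arange(n) * 50
    a = _group(pos, [[0.2] * n] * 5)
    b = _group(pos, [list(0.2 + np.asarray(d))] * 5, prefix="b")
    blocks = dd.build_candidate_blocks(a, b, "Chr1", "CG", min_accessions_per_group=2)
    assert len(blocks) == 1
    return blocks[0]


def brute_force_breakpoint(d):
    """Enumerate every split point, maximising the CUSUM contrast."""
    n = len(d)
    best_k, best_c = None, -1.0
    for k in range(1, n):
        c = math.sqrt(k * (n - k) / n) * abs(np.mean(d[:k]) - np.mean(d[k:]))
        if c > best_c:
            best_k, best_c = k, c
    return best_k, best_c


def test_step_signal_breakpoint_matches_brute_force():
    d = np.array([0.0] * 10 + [0.6] * 10)
    block = _block_from_d(d)
    k_impl, c_impl = dd.best_breakpoint_seeded(block.d)
    k_oracle, c_oracle = brute_force_breakpoint(block.d)
    assert abs(k_impl - 10) <= 1
    assert k_impl == k_oracle
    assert c_impl == pytest.approx(c_oracle, rel=1e-9)


def test_flat_signal_yields_single_segment():
    block = _block_from_d(np.zeros(20))
    assert dd.segment_block(block) == [(0, 20)]


def test_eight_site_block_never_split():
    block = _block_from_d(np.array([0.0] * 4 + [0.6] * 4))
    assert dd.segment_block(block) == [(0, 8)]


def test_embedded_bump_is_isolated():
    # short bump deep inside a long block: seeded search must find it
    d = np.zeros(400)
    d[180:192] = 0.5
    block = _block_from_d(d)
    segs = dd.segment_block(block)
    assert (180, 192) in segs


# ---------------------------------------------------------------------------
# Mann-Whitney leaf test vs exact U-distribution enumeration
# ---------------------------------------------------------------------------


def exact_u_counts(n1, n2):
    """Number of rank subsets per rank-sum via dynamic programming."""
    n = n1 + n2
    ways = [[0] * (n * n1 + 1) for _ in range(n1 + 1)]
    ways[0][0] = 1
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            row, prev = ways[k], ways[k - 1]
            for s in range(n * n1, rank - 1, -1):
                row[s] += prev[s - rank]
    return ways[n1]


def exact_mwu_two_sided(a, b):
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    counts = exact_u_counts(n1, n2)
    total = math.comb(n1 + n2, n1)
    base = n1 * (n1 + 1) // 2
    dist = {s - base: c for s, c in enumerate(counts) if c}
    p_lo = sum(c for uu, c in dist.items() if uu <= u) / total
    p_hi = sum(c for uu, c in dist.items() if uu >= u) / total
    return min(1.0, 2 * min(p_lo, p_hi))


def test_mwu_equals_exact_enumeration_at_9_12():
    rng = np.random.default_rng(4)
    # complete separation: the smallest attainable two-sided p
    a = rng.uniform(0.0, 0.2, 9)
    b = rng.uniform(0.8, 1.0, 12)
    diff, p = dd.test_segment(a, b)
    assert p == pytest.approx(2 / math.comb(21, 9), rel=1e-12)
    assert p == pytest.approx(exact_mwu_two_sided(a, b), rel=1e-12)
    # random tie-free configurations
    for _ in range(5):
        a = rng.standard_normal(9)
        b = rng.standard_normal(12) + rng.uniform(-1, 1)
        _, p = dd.test_segment(a, b)
        assert p == pytest.approx(exact_mwu_two_sided(a, b), rel=1e-12)


def test_test_segment_identical_and_missing():
    a = np.full(6, 0.3)
    assert dd.test_segment(a, a.copy()) == (0.0, 1.0)
    # a missing accession is dropped from its group only
    b = np.array([0.9] * 6 + [np.nan])
    diff, p = dd.test_segment(np.full(6, 0.1), b)
    assert diff == pytest.approx(0.8)
    # too-sparse group -> skipped
    assert dd.test_segment(np.array([0.1, np.nan, np.nan, np.nan, np.nan, np.nan]), b) is None


def test_group_swap_negates_diff_keeps_p():
    rng = np.random.default_rng(9)
    a = rng.random(9)
    b = rng.random(12)
    d1, p1 = dd.test_segment(a, b)
    d2, p2 = dd.test_segment(b, a)
    assert d2 == pytest.approx(-d1)
    assert p2 == pytest.approx(p1)


# ---------------------------------------------------------------------------
# full caller on planted data
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def planted_run():
    cfg = sd.SimulationConfig(
        seed=31, genome=[("Chr1", 1_500_000)], contexts=["CG"],
        n_planted_dmrs={"Dos:CG": 8}, n_cultivar=0, fraction_dmrs_with={},
    )
    ds, truth = sd.simulate_panel(cfg)
    dmrs = dd.call_dmrs(ds.methylomes, ds.panel, "Dos", "CG")
    return ds, truth, dmrs


def test_planted_dmrs_recovered_with_direction(planted_run):
    ds, truth, dmrs = planted_run
    for p in truth.planted_dmrs:
        hits = [d for d in dmrs if reciprocal_overlap(p.region, d.region)]
        assert hits, f"planted DMR {p.region} not recovered"
        assert hits[0].direction == p.direction


def test_emitted_dmrs_satisfy_filters(planted_run):
    _, _, dmrs = planted_run
    assert dmrs == sorted(dmrs, key=lambda d: (d.region.chrom, d.region.start))
    for d in dmrs:
        assert abs(d.diff) > 0.4
        assert d.q_value < 0.01
        assert d.n_sites >= 8
        assert (d.direction == "increased") == (d.diff > 0)
    # surviving DMRs are mutually non-overlapping
    for i, a in enumerate(dmrs):
        for b in dmrs[i + 1:]:
            assert not a.region.overlaps(b.region)


def test_subthreshold_delta_never_called():
    cfg = sd.SimulationConfig(
        seed=33, genome=[("Chr1", 800_000)], contexts=["CG"],
        n_planted_dmrs={"Dos:CG": 6}, n_cultivar=0, fraction_dmrs_with={},
        planted_delta={"CG": 0.3, "CHG": 0.5, "CHH": 0.25},
    )
    ds, _ = sd.simulate_panel(cfg)
    assert dd.call_dmrs(ds.methylomes, ds.panel, "Dos", "CG") == []
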