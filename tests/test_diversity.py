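from fractions import Fraction

import numpy as np
import pytest

from methfoot import diversity as dv
from methfoot import synthetic_data as sd
from methfoot.types import GenomicRegion, Population

from conftest import make_genotypes


def brute_force_pi_sites(dosages, rows=None):
    """All-pairs expected-difference sums per site, as exact fractions."""
    d = dosages if rows is None else dosages[rows]
    out = []
    for j in range(d.shape[1]):
        col = d[:, j]
        col = col[np.isfinite(col)]
        m = len(col)
        if m < 2:
            out.append(None)
            continue
        total = Fraction(0)
        for i in range(m):
            for k in range(i + 1, m):
                p1 = Fraction(int(col[i]), 2)
                p2 = Fraction(int(col[k]), 2)
                total += p1 + p2 - 2 * p1 * p2
        out.append(total / (m * (m - 1) // 2))
    return out


def test_pi_single_pair_single_site():
    g = make_genotypes([[0.0], [2.0]], positions=[10])
    assert dv.pi_region(g, GenomicRegion("Chr1", 0, 100)).pi == pytest.approx(0.01)


def test_pi_identical_accessions_zero():
    g = make_genotypes(np.full((5, 4), 2.0))
    r = dv.pi_region(g, GenomicRegion("Chr1", 0, 50))
    assert r.pi == 0.0 and r.n_segregating == 0


def test_pi_four_accessions_enumeration():
    g = make_genotypes([[0.0], [0.0], [2.0], [2.0]], positions=[3])
    r = dv.pi_region(g, GenomicRegion("Chr1", 0, 10))
    assert r.pi == pytest.approx((4 / 6) / 10)


def test_pi_matches_brute_force_exactly():
    rng = np.random.default_rng(12)
    n_acc, n_sites = 12, 300
    dosages = rng.choice([0.0, 1.0, 2.0], size=(n_acc, n_sites), p=[0.45, 0.1, 0.45])
    dosages[rng.random(dosages.shape) < 0.05] = np.nan
    positions = np.sort(rng.choice(20_000, n_sites, replace=False))
    g = make_genotypes(dosages, positions=positions)
    oracle = brute_force_pi_sites(dosages)
    for _ in range(60):
        lo = int(rng.integers(0, 19_000))
        region = GenomicRegion("Chr1", lo, lo + int(rng.integers(50, 2000)))
        pos, vals = dv.pi_sites(g, region)
        inside = [j for j in range(n_sites) if lo <= positions[j] < region.end and oracle[j] is not None]
        assert len(vals) == len(inside)
        for v, j in zip(vals, inside):
            assert v == float(oracle[j])  # per-site values are exact rationals
        expect = sum(float(oracle[j]) for j in inside) / len(region)
        assert dv.pi_region(g, region).pi == pytest.approx(expect, rel=1e-12, abs=1e-15)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=4, max_size=4),
            min_size=3,
            max_size=10,
        ),
        st.randoms(use_true_random=False),
    )
    def test_pi_invariances_property(rows, rnd):
        """pi is unchanged by accession reordering and ref/alt relabelling."""
        dosages = np.array(rows, dtype=float)
        positions = np.arange(4) * 7 + 3
        region = GenomicRegion("Chr1", 0, 40)
        base = dv.pi_region(make_genotypes(dosages, positions=positions), region).pi
        order = list(range(len(rows)))
        rnd.shuffle(order)
        shuffled = dv.pi_region(make_genotypes(dosages[order], positions=positions), region).pi
        swapped = dv.pi_region(make_genotypes(2.0 - dosages, positions=positions), region).pi
        assert shuffled == pytest.approx(base, abs=1e-15)
        assert swapped == pytest.approx(base, abs=1e-15)

except ImportError:  # pragma: no cover
    pass


def test_pi_invariant_to_order_and_allele_swap():
    rng = np.random.default_rng(5)
    dosages = rng.choice([0.0, 1.0, 2.0], size=(8, 40))
    positions = np.sort(rng.choice(5000, 40, replace=False))
    region = GenomicRegion("Chr1", 0, 5000)
    base = dv.pi_region(make_genotypes(dosages, positions=positions), region).pi
    perm = rng.permutation(8)
    assert dv.pi_region(make_genotypes(dosages[perm], positions=positions), region).pi == pytest.approx(base)
    assert dv.pi_region(make_genotypes(2.0 - dosages, positions=positions), region).pi == pytest.approx(base)


def test_per_population_pi_exclusions(mini_panel, caplog):
    from methfoot.types import Accession

    panel = mini_panel + [Accession("c0", Population.CULTIVAR)]  # single cultivar
    dosages = np.tile([0.0, 2.0, 0.0, 2.0, 0.0, 2.0, 0.0], (3, 1)).T
    g = make_genotypes(dosages, positions=[5, 15, 25], accessions=[a.id for a in panel])
    with caplog.at_level("WARNING", logger="methfoot"):
        summary, tests = dv.per_population_pi(g, panel, [GenomicRegion("Chr1", 0, 30)])
    assert set(summary["population"]) == {"wild", "landrace"}
    assert summary["mean_pi"].nunique() == 1  # identical genotypes -> equal pi


def test_stratified_with_empty_sets_gives_single_nsr_stratum(small_panel_dataset):
    from methfoot.pipeline import annotation_from_dataset

    ds, _ = small_panel_dataset
    ann = annotation_from_dataset(ds)
    table, anova = dv.stratified_pi_comparison(ds.genotypes, [], [], ann)
    assert set(table["set"]) == {"NSR"}


def test_window_threshold_is_strict():
    # a window at exactly 0.4 group difference belongs to neither class
    from conftest import make_methylome
    from methfoot.types import Accession

    panel = [Accession("w0", Population.WILD), Accession("w1", Population.WILD),
             Accession("l0", Population.LANDRACE), Accession("l1", Population.LANDRACE)]
    pos = np.arange(10, 460, 90)
    # group means 0.0 and 4/10: the difference is the float 0.4 exactly
    meths = {
        "w0": make_methylome(pos, [0] * len(pos), [10] * len(pos)),
        "w1": make_methylome(pos, [0] * len(pos), [10] * len(pos)),
        "l0": make_methylome(pos, [4] * len(pos), [6] * len(pos)),
        "l1": make_methylome(pos, [4] * len(pos), [6] * len(pos)),
    }
    g = make_genotypes(np.zeros((4, 1)), positions=[5], accessions=["w0", "w1", "l0", "l1"])
    win, cmp = dv.methylation_variation_windows(
        meths, panel, Population.WILD, Population.LANDRACE, [("Chr1", 500)], g, "CG"
    )
    assert len(win) == 0  # |0.4 - 0.0| sits exactly on the threshold -> excluded
    # raise one group: difference 0.5 -> high
    meths["l0"] = make_methylome(pos, [6] * len(pos), [4] * len(pos))
    meths["l1"] = make_methylome(pos, [6] * len(pos), [4] * len(pos))
    win, _ = dv.methylation_variation_windows(
        meths, panel, Population.WILD, Population.LANDRACE, [("Chr1", 500)], g, "CG"
    )
    assert list(win["mv_class"]) == ["high"]


def test_null_dmr_level_pi_correlation_is_weak():
    # planted DMRs but structure-free, association-free SNPs: |r| small, p ns
    ok = 0
    for seed in range(8):
        cfg = sd.SimulationConfig(
            seed=200 + seed, genome=[("Chr1", 500_000)], contexts=["CG"],
            n_planted_dmrs={"Dos:CG": 6}, fraction_dmrs_with={}, n_cultivar=0,
            pi_scale={"wild": 1.0, "landrace": 1.0, "cultivar": 1.0},
            mv_mutation_multiplier=1.0,
        )
        ds, truth = sd.simulate_panel(cfg)
        from methfoot import dmr_detection as dd

        dmrs = dd.call_dmrs(ds.methylomes, ds.panel, "Dos", "CG")
        res = dv.dmr_level_pi_correlation(ds.genotypes, dmrs, ds.panel)
        if np.isnan(res["r"]) or (abs(res["r"]) < 0.1 and res["p"] > 0.05) or res["p"] > 0.05:
            ok += 1
    assert ok >= 7  # >= 90%-ish of replicate runs show no association
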