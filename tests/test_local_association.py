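import numpy as np
import pandas as pd
import pytest

from methfoot import local_association as la
from methfoot.types import GenomicRegion

from conftest import make_genotypes

ACC = [f"a{i}" for i in range(12)]


def _levels(values, dmr_id="d1"):
    return pd.DataFrame([values], index=[dmr_id], columns=ACC[: len(values)])


def _coord_matrix(chrom, start, end, fid, values):
    return pd.DataFrame([{"chrom": chrom, "start": start, "end": end, "id": fid,
                          **dict(zip(ACC[: len(values)], values))}])


def test_engine_deterministic_and_skips():
    x = np.linspace(0, 1, 12)
    y = np.linspace(1, 0, 12) + 0.01 * np.sin(np.arange(12))
    e1, e2 = la.PermutationEngine(seed=3), la.PermutationEngine(seed=3)
    assert e1.test(x, y) == e2.test(x, y)
    assert e1.test(x, np.full(12, 2.0)) is None  # zero variance
    assert e1.test(x[:6], y[:6]) is None  # < 10 shared accessions


def test_perfect_correlation_is_significant():
    x = np.linspace(0.05, 0.95, 12)
    r, nex = la.PermutationEngine(seed=1).test(x, x.copy())
    assert r == pytest.approx(1.0)
    assert nex == 0


def test_sirna_and_te_share_one_engine_code_path():
    # the same 0/1 vector fed as an siRNA RPM and as a TE variant must give
    # identical r and exceedance counts
    rng = np.random.default_rng(6)
    x = np.concatenate([rng.uniform(0, 0.2, 5), rng.uniform(0.6, 0.9, 7)])
    y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1], dtype=float)
    region = GenomicRegion("Chr1", 1000, 2000)
    levels = _levels(x, dmr_id=str(region))
    eng = la.PermutationEngine(seed=2)
    s = la.associate_sirna([region], levels, _coord_matrix("Chr1", 900, 1500, "f", y), engine=eng)
    t = la.associate_te([region], levels, _coord_matrix("Chr1", 1200, 1201, "f", y), engine=eng)
    assert len(s) == len(t) == 1
    assert s[0].r == pytest.approx(t[0].r)
    assert s[0].n_perm_exceed == t[0].n_perm_exceed


def test_constant_rpm_and_all_carrier_te_skipped():
    region = GenomicRegion("Chr1", 0, 100)
    levels = _levels(np.linspace(0, 1, 12), dmr_id=str(region))
    assert la.associate_sirna([region], levels, _coord_matrix("Chr1", 0, 50, "c", [5.0] * 12)) == []
    assert la.associate_te([region], levels, _coord_matrix("Chr1", 200, 201, "t", [1.0] * 12)) == []


def test_point_biserial_matches_closed_form():
    # carriers at 0.9 (7 of 12), non-carriers at 0.1: textbook point-biserial
    y = np.array([1] * 7 + [0] * 5, dtype=float)
    x = np.where(y == 1, 0.9, 0.1)
    region = GenomicRegion("Chr1", 0, 100)
    res = la.associate_te([region], _levels(x, str(region)),
                          _coord_matrix("Chr1", 150, 151, "t", y))
    assert len(res) == 1
    p, q = 7 / 12, 5 / 12
    expect = (0.9 - 0.1) * np.sqrt(p * q) / x.std()
    assert res[0].r == pytest.approx(expect, rel=1e-12)
    assert res[0].r == pytest.approx(1.0)
    assert res[0].significant
    assert res[0].distance == 51  # edge-to-variant distance


def test_te_closest_variant_within_max_dist():
    region = GenomicRegion("Chr1", 1000, 2000)
    x = np.linspace(0, 1, 12)
    far = _coord_matrix("Chr1", 50_000, 50_001, "far", [0, 1] * 6)
    assert la.associate_te([region], _levels(x, str(region)), far, max_dist=20_000) == []
    res = la.associate_te([region], _levels(x, str(region)), far, max_dist=60_000)
    assert len(res) == 1 and res[0].factor_id == "far"


def test_te_distance_bins_quintiles():
    results = [
        la.AssociationResult("d", "te", f"t{i}", r=1.0 - 0.002 * i, n_perm_exceed=0,
                             significant=True, n_shared=12, distance=i * 100)
        for i in range(25)
    ]
    bins = la.te_distance_bins(results)
    assert len(bins) == 5 and bins["n"].sum() == 25
    assert bins["mean_abs_r"].is_monotonic_decreasing


def test_snp_monomorphic_window_and_mac_filter():
    region = GenomicRegion("Chr1", 100, 200)
    x = np.linspace(0, 1, 12)
    mono = make_genotypes(np.zeros((12, 3)), positions=[120, 150, 180], accessions=ACC)
    assert la.associate_snp([region], _levels(x, str(region)), mono) == []
    # a single homozygous carrier = 2 alt alleles < 3 -> still no test
    low = np.zeros((12, 1)); low[0, 0] = 2.0
    g = make_genotypes(low, positions=[150], accessions=ACC)
    assert la.associate_snp([region], _levels(x, str(region)), g) == []


def test_snp_perfect_partition_significant():
    # panel-sized groups: a permutation can only reproduce |r|=1 by
    # recreating the exact 0/2 split, which 1000 draws will not do at n=45
    acc45 = [f"a{i}" for i in range(45)]
    y = np.array([0.0] * 20 + [2.0] * 25)
    x = np.where(y == 2.0, 0.8, 0.1)
    region = GenomicRegion("Chr1", 100, 200)
    g = make_genotypes(y[:, None], positions=[150], accessions=acc45)
    levels = pd.DataFrame([x], index=[str(region)], columns=acc45)
    res = la.associate_snp([region], levels, g)
    assert len(res) == 1 and res[0].significant and abs(res[0].r) == pytest.approx(1.0)


def test_snp_bonferroni_blocks_windows_with_too_many_snps():
    # 60 SNPs tested: rank-p floor (1/1001) * 60 > 0.05, nothing can pass
    rng = np.random.default_rng(3)
    y = np.array([0.0] * 5 + [2.0] * 7)
    x = np.where(y == 2.0, 0.8, 0.1)
    dos = np.column_stack([y] + [rng.choice([0.0, 2.0], 12) for _ in range(59)])
    keep = [j for j in range(60) if min(dos[:, j].sum(), 24 - dos[:, j].sum()) >= 6]
    g = make_genotypes(dos[:, keep], positions=np.arange(len(keep)) + 110, accessions=ACC)
    region = GenomicRegion("Chr1", 100, 200)
    res = la.associate_snp([region], _levels(x, str(region)), g, window=500)
    assert len(res) == len(keep) > 50
    assert not any(r.significant for r in res)


def test_pure_dmr_set_semantics():
    from methfoot.types import DMR, Comparison, Context

    dmrs = [
        DMR(GenomicRegion("Chr1", i * 1000, i * 1000 + 500), Context.CG, Comparison.DOS,
            10, 0.1, 0.6, 0.5, 1e-5, 1e-3)
        for i in range(4)
    ]
    none_sig = [la.AssociationResult(dmrs[0].dmr_id, "sirna", "s", 0.2, 500, False, 12)]
    pure, summary = la.pure_dmrs(none_sig, dmrs)
    assert len(pure) == 4 and summary["n_associated"] == 0

    multi = [
        la.AssociationResult(dmrs[0].dmr_id, "sirna", "s", 0.9, 0, True, 12),
        la.AssociationResult(dmrs[0].dmr_id, "snp", "x", 0.8, 0, True, 12),
    ]
    pure, summary = la.pure_dmrs(multi, dmrs)
    assert len(pure) == 3
    assert summary["n_associated"] == 1  # counted once despite two factors
    assert summary["combinations"] == {"sirna+snp": 1}
    assert summary["per_factor"]["te"] == 0


def test_associated_fraction_recovers_planted_rate():
    # 25% of planted DMRs carry an siRNA association; in a structure-free
    # world (equal allele-frequency scaling, no mutation-rate boost) the
    # recovered associated fraction should sit within a few points of 25%
    from methfoot import dmr_detection as dd
    from methfoot import synthetic_data as sd

    cfg = sd.SimulationConfig(
        seed=77, genome=[("Chr1", 4_000_000)], contexts=["CG"],
        n_planted_dmrs={"Dos:CG": 40},
        fraction_dmrs_with={"sirna": 0.25},
        pi_scale={"wild": 1.0, "landrace": 1.0, "cultivar": 1.0},
        mv_mutation_multiplier=1.0,
    )
    ds, truth = sd.simulate_panel(cfg)
    dmrs = dd.call_dmrs(ds.methylomes, ds.panel, "Dos", "CG")
    assert len(dmrs) >= 36
    levels = la.dmr_level_matrix(dmrs, ds.methylomes)
    eng = la.PermutationEngine(seed=78)
    results = (
        la.associate_sirna(dmrs, levels, ds.sirna, engine=eng)
        + la.associate_te(dmrs, levels, ds.te_variants, engine=eng)
        + la.associate_snp(dmrs, levels, ds.genotypes, engine=eng)
    )
    pure, summary = la.pure_dmrs(results, dmrs)
    planted_rate = sum(
        1 for a in truth.planted_associations if a.factor_type == "sirna"
    ) / len(truth.planted_dmrs)
    assert abs(summary["fraction_associated"] - planted_rate) <= 0.07


def test_correlate_expression_sign_skip_and_null():
    rng = np.random.default_rng(9)
    x = np.linspace(0.1, 0.9, 12)
    levels = _levels(x, "d1")
    n_null = 60
    expr = pd.DataFrame(
        rng.lognormal(2, 1, (n_null, 12)), columns=ACC,
        index=pd.Index([f"g{i}" for i in range(n_null)], name="id"),
    )
    mapping = {f"g{i}": "d1" for i in range(n_null)} | {"absent": "d1"}
    # pure null: at most 5% of tested genes survive BH
    out_null = la.correlate_expression(mapping, expr, levels)
    assert "absent" not in set(out_null["gene"])
    assert (out_null["q"] < 0.05).mean() <= 0.05
    # a perfectly anti-correlated gene is recovered with r = -1
    expr.loc["g0"] = 2 ** (-x * 10 + 12) - 1.0  # log2(e+1) = -10x + 12 exactly
    out = la.correlate_expression(mapping, expr, levels).set_index("gene")
    assert out.loc["g0", "r"] == pytest.approx(-1.0)
    assert out.loc["g0", "q"] < 0.05
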