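"""Nei-Li nucleotide diversity and its stratification over the methylome.

pi of a region is the sum over segregating sites of the average pairwise
per-site difference between accessions, divided by the region length in
bp (monomorphic sites contribute zero, which keeps values comparable
across region sets).  Dosages are allele frequencies per individual
(0, 1, 2 alt alleles -> p = d/2); the expected difference between two
individuals at one site is p_i + p_j - 2 p_i p_j, i.e. 0/1 for
homozygous pairs and 0.5 when a heterozygote is involved.  Pairs with a
missing genotype at a site are dropped from that site's pair count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import IntervalSet
from .io_formats import AnnotationSet, GenotypeMatrix, MethylomeTable
from .dmr_landscape import assign_composition
from .methylation_calling import DEFAULT_MIN_DEPTH
from .types import Accession, Context, GenomicRegion, Population

logger = logging.getLogger("methfoot")

MV_THRESHOLD = 0.4
WINDOW_BP = 500


@dataclass(frozen=True)
class PiResult:
    pi: float
    n_segregating: int

    def __float__(self) -> float:
        return self.pi


def pi_sites(
    g: GenotypeMatrix, region: GenomicRegion, accession_subset: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site average pairwise difference for sites inside a region.

    Each per-site value is an exact integer ratio: with integer dosages
    d and S1 = sum d, S2 = sum d^2 over the m non-missing accessions,
    sum of pairwise differences * 4 = 2(m-1)S1 - S1^2 + S2, and the
    per-site pi is that divided by 2 m (m-1).
    """
    idx = g.sites_in(region)
    rows = (
        np.array([g.accessions.index(a) for a in accession_subset])
        if accession_subset is not None
        else np.arange(len(g.accessions))
    )
    vals, positions = [], []
    for j in idx:
        d = g.dosages[rows, j]
        d = d[np.isfinite(d)]
        m = len(d)
        if m < 2:
            continue
        s1 = int(d.sum())
        s2 = int((d * d).sum())
        num4 = 2 * (m - 1) * s1 - s1 * s1 + s2
        vals.append(num4 / (2 * m * (m - 1)))
        positions.append(int(g.pos0[j]))
    return np.array(positions, dtype=np.int64), np.array(vals, dtype=float)


def pi_region(
    g: GenotypeMatrix, region: GenomicRegion, accession_subset: list[str] | None = None
) -> PiResult:
    """Per-bp Nei-Li diversity of a region (0 when no usable site)."""
    _, vals = pi_sites(g, region, accession_subset)
    total = 0.0
    for v in vals:  # fixed ascending-position order
        total += v
    return PiResult(pi=total / len(region), n_segregating=int((vals > 0).sum()))


# ---------------------------------------------------------------------------
# stratified comparisons
# ---------------------------------------------------------------------------


def build_nsr(
    dmr_regions: list[GenomicRegion],
    dsr_regions: list[GenomicRegion],
    chrom_lengths: dict[str, int],
    min_len: int = 200,
) -> list[GenomicRegion]:
    """Non-selected regions: the genome minus DMRs minus DSRs."""
    out = []
    for chrom, length in chrom_lengths.items():
        cover = IntervalSet.empty()
        for r in dmr_regions + dsr_regions:
            if r.chrom == chrom:
                cover = cover.union(IntervalSet([r.start], [r.end]))
        for r in cover.complement(length).to_regions(chrom):
            if len(r) >= min_len:
                out.append(r)
    return out


def stratified_pi_comparison(
    g: GenotypeMatrix,
    dmr_regions: list[GenomicRegion],
    dsr_regions: list[GenomicRegion],
    ann: AnnotationSet,
    accession_subset: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean pi per (region set x composition) with one-way ANOVA per composition."""
    sets = {"DMR": dmr_regions, "DSR": dsr_regions}
    sets["NSR"] = build_nsr(dmr_regions, dsr_regions, ann.chrom_lengths)
    rows = []
    for name, regions in sets.items():
        for r in regions:
            comp, _ = assign_composition(r, ann)
            rows.append(
                {
                    "set": name,
                    "composition": comp,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "pi": pi_region(g, r, accession_subset).pi,
                }
            )
    table = pd.DataFrame(rows)
    anova: dict[str, float] = {}
    for comp, sub in table.groupby("composition"):
        groups = [v["pi"].to_numpy() for _, v in sub.groupby("set") if len(v) >= 2]
        if len(groups) >= 2:
            anova[comp] = float(stats.f_oneway(*groups).pvalue)
        else:
            logger.warning("stratum %r too sparse for ANOVA, omitted", comp)
    return table, anova


# ---------------------------------------------------------------------------
# methylation-variation windows
# ---------------------------------------------------------------------------


def _window_levels(
    methylomes: list[MethylomeTable],
    chrom: str,
    length: int,
    context: Context,
    window_bp: int,
    min_depth: int,
) -> np.ndarray:
    """(n_windows, n_acc) weighted methylation per tiling window."""
    n_win = int(np.ceil(length / window_bp))
    meth = np.zeros((n_win, len(methylomes)))
    tot = np.zeros_like(meth)
    for k, m in enumerate(methylomes):
        df = m.subset(chrom=chrom, context=context)
        if not len(df):
            continue
        depth = (df["n_meth"] + df["n_unmeth"]).to_numpy()
        ok = depth >= min_depth
        w = (df["pos0"].to_numpy()[ok] // window_bp).astype(int)
        meth[:, k] = np.bincount(w, weights=df["n_meth"].to_numpy()[ok], minlength=n_win)
        tot[:, k] = np.bincount(w, weights=depth[ok], minlength=n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)


def _nanmean_rows(x: np.ndarray) -> np.ndarray:
    """Row means over finite entries; NaN (no warning) for empty rows."""
    finite = np.isfinite(x)
    cnt = finite.sum(axis=1)
    sums = np.where(finite, x, 0.0).sum(axis=1)
    return np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)


def methylation_variation_windows(
    methylomes: dict[str, MethylomeTable],
    panel: list[Accession],
    group_a: Population,
    group_b: Population,
    genome: list[tuple[str, int]],
    g: GenotypeMatrix,
    context: Context | str = Context.CG,
    window_bp: int = WINDOW_BP,
    threshold: float = MV_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    ann: AnnotationSet | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Tile the genome in 500-bp windows, classify by |group mean difference|.

    Windows with |difference| > threshold are "high", < threshold "low";
    equality is excluded.  Returns per-window stats and a t-test of pi
    between the two classes (overall and per composition when annotation
    is supplied).
    """
    context = Context(context)
    ids_a = [a.id for a in panel if a.population == group_a]
    ids_b = [a.id for a in panel if a.population == group_b]
    rows = []
    for chrom, length in genome:
        la = _window_levels([methylomes[i] for i in ids_a], chrom, length, context, window_bp, min_depth)
        lb = _window_levels([methylomes[i] for i in ids_b], chrom, length, context, window_bp, min_depth)
        ma = _nanmean_rows(la)
        mb = _nanmean_rows(lb)
        for w in range(la.shape[0]):
            if not (np.isfinite(ma[w]) and np.isfinite(mb[w])):
                continue
            var = abs(mb[w] - ma[w])
            if var > threshold:
                mv = "high"
            elif var < threshold:
                mv = "low"
            else:
                continue  # exactly at the threshold: neither class
            start = w * window_bp
            reg = GenomicRegion(chrom, start, min(start + window_bp, length))
            row = {
                "chrom": chrom,
                "start": reg.start,
                "end": reg.end,
                "meth_variation": float(var),
                "mv_class": mv,
                "pi": pi_region(g, reg).pi,
            }
            if ann is not None:
                row["composition"] = assign_composition(reg, ann)[0]
            rows.append(row)
    windows = pd.DataFrame(rows)
    comparison: dict = {}
    if len(windows):
        hi = windows.loc[windows["mv_class"] == "high", "pi"]
        lo = windows.loc[windows["mv_class"] == "low", "pi"]
        if len(hi) >= 2 and len(lo) >= 2:
            t = stats.ttest_ind(hi, lo, equal_var=False)
            comparison["overall"] = {
                "mean_pi_high": float(hi.mean()),
                "mean_pi_low": float(lo.mean()),
                "t": float(t.statistic),
                "p": float(t.pvalue),
            }
        if ann is not None:
            for comp, sub in windows.groupby("composition"):
                h = sub.loc[sub["mv_class"] == "high", "pi"]
                l = sub.loc[sub["mv_class"] == "low", "pi"]
                if len(h) >= 2 and len(l) >= 2:
                    t = stats.ttest_ind(h, l, equal_var=False)
                    comparison[comp] = {
                        "mean_pi_high": float(h.mean()),
                        "mean_pi_low": float(l.mean()),
                        "t": float(t.statistic),
                        "p": float(t.pvalue),
                    }
    return windows, comparison


def per_population_pi(
    g: GenotypeMatrix, panel: list[Accession], region_set: list[GenomicRegion]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean pi per population over a region set, with pairwise Welch t-tests."""
    by_pop: dict[str, np.ndarray] = {}
    for pop in Population:
        ids = [a.id for a in panel if a.population == pop]
        if len(ids) < 2:
            logger.warning("population %r has < 2 accessions, excluded from pi", pop.value)
            continue
        by_pop[pop.value] = np.array([pi_region(g, r, ids).pi for r in region_set])
    summary = pd.DataFrame(
        [{"population": k, "n_regions": len(v), "mean_pi": float(v.mean())} for k, v in by_pop.items()]
    )
    pw = []
    pops = list(by_pop)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            t = stats.ttest_ind(by_pop[pops[i]], by_pop[pops[j]], equal_var=False)
            pw.append({"pop_a": pops[i], "pop_b": pops[j], "t": float(t.statistic), "p": float(t.pvalue)})
    return summary, pd.DataFrame(pw)


def dmr_level_pi_correlation(
    g: GenotypeMatrix, dmrs, panel: list[Accession]
) -> dict[str, float]:
    """Pearson r between DMR effect size |diff| and the pi change between
    the compared populations (interpretive report; the underlying study's
    exact quantity is not fully specified)."""
    from .types import COMPARISON_GROUPS

    xs, ys = [], []
    for d in dmrs:
        pop_a, pop_b = COMPARISON_GROUPS[d.comparison]
        ids_a = [a.id for a in panel if a.population == pop_a]
        ids_b = [a.id for a in panel if a.population == pop_b]
        pa = pi_region(g, d.region, ids_a).pi
        pb = pi_region(g, d.region, ids_b).pi
        xs.append(abs(d.diff))
        ys.append(pb - pa)
    if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": len(xs)}
    r, p = stats.pearsonr(xs, ys)
    return {"r": float(r), "p": float(p), "n": len(xs)}
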