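"""Local association of DMR methylation with siRNA, TE and SNP variation.

Each DMR's per-accession weighted methylation vector is correlated
(Pearson) with overlapping siRNA cluster RPMs, the closest TE variant's
presence/absence vector (point-biserial), and nearby SNP dosages.
Significance uses a permutation-exceedance rule: the accession labels of
the factor vector are permuted 1000 times, and an association is
significant only when no permutation reaches the observed |r|
(p < 1/1000).  SNPs additionally carry a per-DMR Bonferroni correction
on the rank-based permutation p.  DMRs with no significant association
of any kind are "pure DMRs" — candidate pure epialleles.

One permutation engine backs all three factor types: the same seeded
label permutations are reused across every pair in a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenotypeMatrix
from .types import DMR, GenomicRegion

logger = logging.getLogger("methfoot")

N_PERM = 1000
MIN_SHARED_ACCESSIONS = 10
TE_MAX_DIST = 20_000
SNP_WINDOW = 20_000  # +/- bp around the DMR; see run log for rationale
SNP_MIN_MAC = 3


@dataclass
class AssociationResult:
    dmr_id: str
    factor_type: str  # sirna | te | snp | expression
    factor_id: str
    r: float
    n_perm_exceed: int
    significant: bool
    n_shared: int
    distance: int = 0

    @property
    def perm_p(self) -> float:
        return (self.n_perm_exceed + 1) / (N_PERM + 1)


class PermutationEngine:
    """Seeded label permutations shared across all pairs of a run."""

    def __init__(self, n_perm: int = N_PERM, seed: int = 0, one_sided: bool = False):
        self.n_perm = n_perm
        self.seed = seed
        self.one_sided = one_sided
        self._perm_cache: dict[int, np.ndarray] = {}

    def _perms(self, m: int) -> np.ndarray:
        if m not in self._perm_cache:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, m]))
            self._perm_cache[m] = np.argsort(rng.random((self.n_perm, m)), axis=1)
        return self._perm_cache[m]

    def test(self, x: np.ndarray, y: np.ndarray) -> tuple[float, int] | None:
        """Observed r and exceedance count; None when the pair is untestable."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        shared = np.isfinite(x) & np.isfinite(y)
        m = int(shared.sum())
        if m < MIN_SHARED_ACCESSIONS:
            return None
        xs, ys = x[shared], y[shared]
        if xs.std() == 0 or ys.std() == 0:
            return None
        xs = (xs - xs.mean()) / xs.std()
        ys = (ys - ys.mean()) / ys.std()
        r_obs = float(xs @ ys / m)
        r_perm = (ys[self._perms(m)] @ xs) / m
        if self.one_sided:
            n_exceed = int(np.sum(r_perm >= r_obs - 1e-12))
        else:
            n_exceed = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        return r_obs, n_exceed


def _dmr_region(d) -> GenomicRegion:
    return d.region if isinstance(d, DMR) else d


def _dmr_id(d) -> str:
    return d.dmr_id if isinstance(d, DMR) else str(d)


def associate_sirna(
    dmrs: list[DMR],
    dmr_levels: pd.DataFrame,
    sirna: pd.DataFrame,
    n_perm: int = N_PERM,
    seed: int = 0,
    engine: PermutationEngine | None = None,
) -> list[AssociationResult]:
    """Test every siRNA cluster overlapping (>= 1 bp) each DMR.

    dmr_levels: DataFrame indexed by dmr_id with one column per accession.
    sirna: coord matrix (chrom/start/end/id + accession RPM columns).
    """
    eng = engine or PermutationEngine(n_perm, seed)
    acc = [c for c in sirna.columns if c not in ("chrom", "start", "end", "id")]
    out = []
    for d in dmrs:
        reg = _dmr_region(d)
        x = dmr_levels.loc[_dmr_id(d), acc].to_numpy(dtype=float)
        hits = sirna[
            (sirna["chrom"] == reg.chrom)
            & (sirna["start"] < reg.end)
            & (sirna["end"] > reg.start)
        ]
        for row in hits.itertuples(index=False):
            y = np.array([getattr(row, a) for a in acc], dtype=float)
            res = eng.test(x, y)
            if res is None:
                logger.debug("sirna pair %s/%s skipped", _dmr_id(d), row.id)
                continue
            r, nex = res
            out.append(
                AssociationResult(
                    _dmr_id(d), "sirna", row.id, r, nex, nex == 0,
                    int(np.isfinite(x).sum()),
                )
            )
    return out


def associate_te(
    dmrs: list[DMR],
    dmr_levels: pd.DataFrame,
    te_variants: pd.DataFrame,
    max_dist: int = TE_MAX_DIST,
    n_perm: int = N_PERM,
    seed: int = 0,
    engine: PermutationEngine | None = None,
) -> list[AssociationResult]:
    """Point-biserial test of each DMR against its closest TE variant.

    te_variants: coord matrix with one 0/1 column per accession.  The
    distance is bp from the DMR edge to the variant position (0 inside).
    """
    eng = engine or PermutationEngine(n_perm, seed)
    acc = [c for c in te_variants.columns if c not in ("chrom", "start", "end", "id")]
    out = []
    for d in dmrs:
        reg = _dmr_region(d)
        cand = te_variants[te_variants["chrom"] == reg.chrom]
        if not len(cand):
            continue
        pos = cand["start"].to_numpy()
        dist = np.where(
            pos < reg.start, reg.start - pos, np.where(pos >= reg.end, pos - reg.end + 1, 0)
        )
        order = np.argsort(dist, kind="stable")
        best = None
        for i in order:
            if dist[i] > max_dist:
                break
            y = cand.iloc[i][acc].to_numpy(dtype=float)
            vals = y[np.isfinite(y)]
            if len(np.unique(vals)) < 2:
                continue  # all present or all absent: untestable
            best = (cand.iloc[i]["id"], int(dist[i]), y)
            break
        if best is None:
            continue
        tid, dbest, y = best
        x = dmr_levels.loc[_dmr_id(d), acc].to_numpy(dtype=float)
        res = eng.test(x, y)
        if res is None:
            continue
        r, nex = res
        out.append(
            AssociationResult(
                _dmr_id(d), "te", tid, r, nex, nex == 0,
                int(np.isfinite(x).sum()), distance=dbest,
            )
        )
    return out


def te_distance_bins(results: list[AssociationResult], n_bins: int = 5) -> pd.DataFrame:
    """Mean |r| per distance quintile of DMR/TE pairs."""
    if not results:
        return pd.DataFrame(columns=["bin", "d_min", "d_max", "n", "mean_abs_r"])
    dist = np.array([r.distance for r in results], dtype=float)
    absr = np.array([abs(r.r) for r in results])
    edges = np.quantile(dist, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1
    rows = []
    for b in range(n_bins):
        sel = (dist >= edges[b]) & (dist < edges[b + 1])
        rows.append(
            {
                "bin": b + 1,
                "d_min": float(edges[b]),
                "d_max": float(edges[b + 1]),
                "n": int(sel.sum()),
                "mean_abs_r": float(absr[sel].mean()) if sel.any() else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def associate_snp(
    dmrs: list[DMR],
    dmr_levels: pd.DataFrame,
    g: GenotypeMatrix,
    window: int = SNP_WINDOW,
    n_perm: int = N_PERM,
    seed: int = 0,
    min_mac: int = SNP_MIN_MAC,
    engine: PermutationEngine | None = None,
) -> list[AssociationResult]:
    """Dosage-Pearson tests of each DMR against SNPs within +/- window bp.

    A SNP is significant for a DMR when no permutation reaches |r_obs|
    AND its rank-based permutation p times the number of SNPs tested for
    that DMR stays below 0.05 (per-DMR Bonferroni).
    """
    eng = engine or PermutationEngine(n_perm, seed)
    acc = list(dmr_levels.columns)
    order = [g.accessions.index(a) for a in acc]
    out = []
    for d in dmrs:
        reg = _dmr_region(d)
        win = GenomicRegion(reg.chrom, max(0, reg.start - window), reg.end + window)
        idx = g.sites_in(win)
        if not len(idx):
            continue
        x = dmr_levels.loc[_dmr_id(d), acc].to_numpy(dtype=float)
        tested = []
        for j in idx:
            y = g.dosages[order, j]
            valid = y[np.isfinite(y) & np.isfinite(x)]
            if not len(valid):
                continue
            mac = min(valid.sum(), 2 * len(valid) - valid.sum())
            if mac < min_mac:
                continue
            res = eng.test(x, y)
            if res is None:
                continue
            pos = int(g.pos0[j])
            dist = 0 if reg.start <= pos < reg.end else min(abs(pos - reg.start), abs(pos - reg.end + 1))
            tested.append((f"{reg.chrom}:{pos}", dist, res))
        n_snps = len(tested)
        for sid, dist, (r, nex) in tested:
            rank_p = (nex + 1) / (eng.n_perm + 1)
            sig = nex == 0 and rank_p * n_snps < 0.05
            out.append(
                AssociationResult(
                    _dmr_id(d), "snp", sid, r, nex, sig,
                    int(np.isfinite(x).sum()), distance=dist,
                )
            )
    return out


def pure_dmrs(
    all_results: list[AssociationResult], dmrs: list[DMR]
) -> tuple[list[DMR], dict]:
    """DMRs with no significant association of any factor type, plus summary."""
    sig_by_dmr: dict[str, set[str]] = {}
    for r in all_results:
        if r.significant:
            sig_by_dmr.setdefault(r.dmr_id, set()).add(r.factor_type)
    pure = [d for d in dmrs if not sig_by_dmr.get(_dmr_id(d))]
    combos: dict[str, int] = {}
    for factors in sig_by_dmr.values():
        key = "+".join(sorted(factors))
        combos[key] = combos.get(key, 0) + 1
    n = len(dmrs)
    n_assoc = sum(1 for d in dmrs if sig_by_dmr.get(_dmr_id(d)))
    summary = {
        "n_dmrs": n,
        "n_associated": n_assoc,
        "fraction_associated": n_assoc / n if n else float("nan"),
        "n_pure": len(pure),
        "per_factor": {
            f: sum(1 for s in sig_by_dmr.values() if f in s) for f in ("sirna", "te", "snp")
        },
        "combinations": combos,
    }
    return pure, summary


def correlate_expression(
    gene_to_dmr: dict[str, str],
    expression: pd.DataFrame,
    dmr_levels: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r between log2(FPKM+1) and DMR methylation per pure-DMR gene.

    Genes absent from the expression matrix or with zero variance are
    skipped (recorded); BH correction across tested genes.
    """
    acc = [c for c in dmr_levels.columns if c in expression.columns]
    rows = []
    for gene, dmr_id in gene_to_dmr.items():
        if gene not in expression.index:
            logger.debug("gene %s not in expression matrix, skipped", gene)
            continue
        e = np.log2(expression.loc[gene, acc].to_numpy(dtype=float) + 1.0)
        x = dmr_levels.loc[dmr_id, acc].to_numpy(dtype=float)
        ok = np.isfinite(e) & np.isfinite(x)
        if ok.sum() < 3 or e[ok].std() == 0 or x[ok].std() == 0:
            continue
        r, p = stats.pearsonr(x[ok], e[ok])
        rows.append({"gene": gene, "dmr_id": dmr_id, "r": float(r), "p": float(p), "n": int(ok.sum())})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def dmr_level_matrix(
    dmrs: list[DMR],
    methylomes: dict,
    min_depth: int = 4,
) -> pd.DataFrame:
    """Per-accession weighted methylation of each DMR (rows: dmr_id)."""
    from .methylation_calling import weighted_methylation

    acc_ids = list(methylomes)
    data = {}
    for d in dmrs:
        vals = []
        for a in acc_ids:
            rm = weighted_methylation(methylomes[a], d.region, d.context, min_depth)
            vals.append(np.nan if rm.level is None else rm.level)
        data[d.dmr_id] = vals
    return pd.DataFrame.from_dict(data, orient="index", columns=acc_ids)
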