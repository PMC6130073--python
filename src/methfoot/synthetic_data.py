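"""Synthetic multi-accession methylome panels with planted truth.

The generator emulates the study design the pipeline targets: a selfing
crop panel (9 wild, 12 landrace, 24 cultivar accessions) with WGBS-style
per-cytosine counts in three contexts, a chloroplast non-conversion
control, homozygous SNP genotypes whose diversity decreases from wild to
cultivar, siRNA cluster RPMs, TE presence/absence variants, expression,
gene/TE annotation and a selected-region BED.  DMRs are planted by
shifting the domesticated lineage's true methylation level inside runs
of consecutive context sites; siRNA/TE/SNP associations are planted by
generating factor vectors correlated with the realised per-accession
methylation of a planted DMR.  Every planted feature is recorded in a
TruthSet for recovery testing.

Model notes
-----------
* A site's true methylation level is drawn once per site (heritable
  epigenome) from a context-specific mixture: CG bimodal near 0/1, CHG
  bimodal with a lower, broader methylated mode, CHH uniformly low.
  Accessions add small Gaussian jitter (sd 0.05).
* Observed counts: depth ~ Poisson(depth_mean) floored at 1;
  n_meth ~ Binomial(depth, m + (1 - m) * eps) where eps is the bisulfite
  non-conversion rate (the only conversion error modelled; methylated-C
  under-conversion is folded into the mixture means).
* Genotypes are fully homozygous (dosage 0/2).  Population alt-allele
  frequencies are the global frequency scaled by pi_scale (wild 1.0 >
  landrace 0.6 > cultivar 0.35), which orders nucleotide diversity.
  Inside planted CG/CHG DMRs (the high methylation-variation windows)
  the SNP rate is multiplied by mv_mutation_multiplier.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import GenotypeMatrix, MethylomeTable
from .types import Accession, Comparison, Context, GenomicRegion, Population

CONTEXT_NAMES = [c.value for c in Context]

#: layer order for RNG stream spawning; fixed so every layer is
#: reproducible independently of the others
_LAYERS = (
    "sites",
    "methylomes",
    "chloroplast",
    "snps",
    "sirna",
    "te",
    "expression",
    "annotation",
    "dsr",
    "terms",
)


@dataclass
class SimulationConfig:
    n_wild: int = 9
    n_landrace: int = 12
    n_cultivar: int = 24
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("Chr1", 400_000), ("Chr2", 400_000)]
    )
    contexts: list[str] = field(default_factory=lambda: list(CONTEXT_NAMES))
    #: sites per kb per context
    site_density: dict[str, float] = field(
        default_factory=lambda: {"CG": 12.0, "CHG": 10.0, "CHH": 30.0}
    )
    depth_mean: float = 20.0
    nonconversion_rate: float = 0.005
    #: fraction of sites in the methylated mixture component (CG/CHG) or
    #: the mean of the low component (CHH)
    baseline_level: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.55, "CHG": 0.45, "CHH": 0.05}
    )
    accession_jitter_sd: float = 0.05
    #: planted DMR counts per "Comparison:Context" key
    n_planted_dmrs: dict[str, int] = field(
        default_factory=lambda: {
            f"{cmp.value}:{ctx}": 4 for cmp in Comparison for ctx in CONTEXT_NAMES
        }
    )
    planted_delta: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.5, "CHG": 0.5, "CHH": 0.25}
    )
    planted_n_sites: int = 12
    fraction_dmrs_with: dict[str, float] = field(
        default_factory=lambda: {"sirna": 0.08, "te": 0.08, "snp": 0.08}
    )
    association_r: float = 0.8
    te_plant_max_dist: int = 15_000
    te_decay_span: float = 20_000.0  # linear |r| decay scale with distance
    snp_plant_max_dist: int = 5_000
    snp_per_kb: float = 1.0
    pi_scale: dict[str, float] = field(
        default_factory=lambda: {"wild": 1.0, "landrace": 0.6, "cultivar": 0.35}
    )
    mv_mutation_multiplier: float = 2.0
    gene_every_bp: int = 8_000
    sirna_bg_every_bp: int = 5_000
    te_bg_every_bp: int = 10_000
    n_dsr_per_chrom: int = 5
    dsr_length: int = 20_000
    n_terms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        import logging

        for p in (self.nonconversion_rate, *self.baseline_level.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        # defaults keep planted regions detectable under the DMR thresholds;
        # sub-threshold deltas are allowed deliberately (null-power experiments)
        detect = {"CG": 0.4, "CHG": 0.4, "CHH": 0.2}
        for ctx, thr in detect.items():
            if ctx in self.contexts and self.planted_delta[ctx] <= thr:
                logging.getLogger("methfoot").warning(
                    "planted_delta[%s]=%.2f is at or below the DMR threshold %.1f; "
                    "planted regions will not be callable",
                    ctx, self.planted_delta[ctx], thr,
                )

    def panel(self) -> list[Accession]:
        panel = []
        for pop, n in (
            (Population.WILD, self.n_wild),
            (Population.LANDRACE, self.n_landrace),
            (Population.CULTIVAR, self.n_cultivar),
        ):
            panel.extend(Accession(f"{pop.value[:4]}{i + 1:02d}", pop) for i in range(n))
        return panel


@dataclass
class PlantedDMR:
    region: GenomicRegion
    context: Context
    comparison: Comparison
    direction: str  # increased/decreased in the selected population
    delta: float
    dmr_index: int


@dataclass
class PlantedAssociation:
    dmr_index: int
    factor_type: str  # sirna | te | snp
    factor_id: str
    true_r: float
    distance: int


@dataclass
class TruthSet:
    planted_dmrs: list[PlantedDMR]
    planted_associations: list[PlantedAssociation]
    null_regions: list[GenomicRegion]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    panel: list[Accession]
    methylomes: dict[str, MethylomeTable]
    chloroplast: dict[str, MethylomeTable]
    genotypes: GenotypeMatrix
    sirna: pd.DataFrame  # chrom/start/end/id + accession RPM columns
    te_variants: pd.DataFrame  # chrom/start/end/id + accession 0/1 columns
    expression: pd.DataFrame  # gene_id index x accession columns
    genes: pd.DataFrame  # gene_id, chrom, start, end, exons "s-e;s-e"
    te_bed: pd.DataFrame  # chrom, start, end
    dsr: list[GenomicRegion]
    terms: pd.DataFrame  # gene, term, term_name
    #: realised true per-accession mean methylation of each planted DMR
    planted_levels: dict[int, np.ndarray]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardise a constant vector")
    return (x - x.mean()) / sd


def correlated_factor(x: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Latent vector with population correlation r to x (standardised)."""
    z = _standardize(x)
    noise = rng.standard_normal(len(z))
    noise = _standardize(noise)
    return r * z + np.sqrt(max(0.0, 1.0 - r * r)) * noise


def correlated_rpm(x: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Non-negative siRNA RPM vector correlated with x."""
    y = correlated_factor(x, r, rng)
    return np.maximum(100.0 + 25.0 * y, 0.0)


def correlated_presence(x: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """0/1 presence vector whose sample point-biserial correlation with x
    approximates r.

    Thresholding a latent Gaussian attenuates the realised correlation
    well below the latent one when x is bimodal, so instead the vector
    starts from the cutoff split of x with the highest achievable
    correlation and single labels are flipped greedily (in seeded random
    order) until the realised r is as close to the target as one flip
    allows.  When even the best split is below |r| it is returned as is.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sign = 1.0 if r >= 0 else -1.0
    target = abs(r)
    order = np.argsort(x)
    best_y, best_r = None, -1.0
    for k in range(1, n):
        y = np.zeros(n)
        y[order[k:]] = 1.0
        c = float(np.corrcoef(x, y)[0, 1])
        if c > best_r:
            best_r, best_y = c, y
    y, cur = best_y, best_r
    while cur > target:
        improved = False
        for i in rng.permutation(n):
            y2 = y.copy()
            y2[i] = 1.0 - y2[i]
            if len(np.unique(y2)) < 2:
                continue
            c2 = float(np.corrcoef(x, y2)[0, 1])
            if abs(c2 - target) < abs(cur - target):
                y, cur = y2, c2
                improved = True
                break
        if not improved:
            break
    if sign < 0:
        y = 1.0 - y
    return y


def _mixture_levels(context: str, n: int, frac_high: float, rng: np.random.Generator) -> np.ndarray:
    if context == "CG":
        hi = rng.beta(18, 3, n)
        lo = rng.beta(1.5, 30, n)
    elif context == "CHG":
        hi = rng.beta(10, 4, n)
        lo = rng.beta(1.5, 30, n)
    else:  # CHH: uniformly low; frac_high is the mean of the low mode
        b = max(1.0 / max(frac_high, 1e-6) - 1.0, 1.0)
        return rng.beta(1.0, b, n)
    return np.where(rng.random(n) < frac_high, hi, lo)


def simulate_chloroplast_control(
    epsilon: float,
    depth_mean: float,
    n_sites: int,
    seed: int | np.random.Generator,
    accession: str = "",
) -> MethylomeTable:
    """Cytosine report for a truly unmethylated control genome.

    n_meth ~ Binomial(depth, epsilon) at every site.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos0 = np.sort(rng.choice(n_sites * 20, size=n_sites, replace=False))
    depth = np.maximum(rng.poisson(depth_mean, n_sites), 1)
    n_meth = rng.binomial(depth, epsilon)
    ctx = rng.choice(CONTEXT_NAMES, n_sites)
    df = pd.DataFrame(
        {
            "chrom": "ChrC",
            "pos0": pos0,
            "strand": np.where(rng.random(n_sites) < 0.5, "+", "-"),
            "context": ctx,
            "n_meth": n_meth,
            "n_unmeth": depth - n_meth,
        }
    )
    return MethylomeTable(df, accession=accession)


# ---------------------------------------------------------------------------
# the panel simulator
# ---------------------------------------------------------------------------


def simulate_panel(
    config: SimulationConfig, out_dir: str | os.PathLike | None = None
) -> tuple[SimulatedDataset, TruthSet]:
    """Generate the full dataset plus its truth tables.

    With `out_dir` set, every layer is written through the io_formats
    writers (same seed twice gives byte-identical files).
    """
    cfg = config
    panel = cfg.panel()
    acc_ids = [a.id for a in panel]
    pops = np.array([a.population.value for a in panel])
    n_acc = len(panel)
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(_LAYERS, np.random.SeedSequence(cfg.seed).spawn(len(_LAYERS)))
    }

    # --- cytosine site grids, one per chromosome ------------------------
    rng = streams["sites"]
    grids: dict[str, pd.DataFrame] = {}
    for chrom, length in cfg.genome:
        total_density = sum(cfg.site_density[c] for c in cfg.contexts) / 1000.0
        n_sites = rng.poisson(length * total_density)
        pos = np.sort(rng.choice(length, size=min(n_sites, length), replace=False))
        probs = np.array([cfg.site_density[c] for c in cfg.contexts], dtype=float)
        probs /= probs.sum()
        ctx = rng.choice(cfg.contexts, size=len(pos), p=probs)
        strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        grids[chrom] = pd.DataFrame(
            {"pos0": pos, "context": ctx, "strand": strand}
        )

    # --- plant DMRs ------------------------------------------------------
    planted: list[PlantedDMR] = []
    rng_m = streams["methylomes"]
    occupied: list[GenomicRegion] = []
    dmr_index = 0
    for cmp in Comparison:
        for ctx in cfg.contexts:
            want = cfg.n_planted_dmrs.get(f"{cmp.value}:{ctx}", 0)
            placed = 0
            tries = 0
            while placed < want:
                tries += 1
                if tries > 200 * max(want, 1):
                    raise RuntimeError(
                        "could not place planted DMRs without overlap; "
                        "reduce n_planted_dmrs or enlarge the genome"
                    )
                chrom = cfg.genome[rng_m.integers(len(cfg.genome))][0]
                g = grids[chrom]
                cpos = g.loc[g["context"] == ctx, "pos0"].to_numpy()
                if len(cpos) < cfg.planted_n_sites + 2:
                    continue
                i = int(rng_m.integers(0, len(cpos) - cfg.planted_n_sites))
                run = cpos[i : i + cfg.planted_n_sites]
                if np.any(np.diff(run) >= 300):
                    continue
                region = GenomicRegion(chrom, int(run[0]), int(run[-1]) + 1)
                pad = GenomicRegion(chrom, max(0, region.start - 500), region.end + 500)
                if any(pad.overlaps(o) for o in occupied):
                    continue
                direction = "increased" if rng_m.random() < 0.5 else "decreased"
                planted.append(
                    PlantedDMR(region, Context(ctx), cmp, direction,
                               cfg.planted_delta[ctx], dmr_index)
                )
                occupied.append(pad)
                dmr_index += 1
                placed += 1

    # --- true levels and observed counts --------------------------------
    shifted_pops = {
        Comparison.DOS: {"landrace", "cultivar"},  # domesticated lineage
        Comparison.IMP: {"cultivar"},
    }
    methylomes: dict[str, MethylomeTable] = {a: [] for a in acc_ids}  # type: ignore[assignment]
    planted_levels: dict[int, np.ndarray] = {}
    eps = cfg.nonconversion_rate
    for chrom, _length in cfg.genome:
        g = grids[chrom]
        n = len(g)
        m_site = np.empty(n)
        for ctx in cfg.contexts:
            mask = (g["context"] == ctx).to_numpy()
            m_site[mask] = _mixture_levels(ctx, int(mask.sum()), cfg.baseline_level[ctx], rng_m)
        # population-level truth: (n_sites, n_acc)
        m_pop = np.tile(m_site[:, None], (1, n_acc))
        for p in planted:
            if p.region.chrom != chrom:
                continue
            sel = (
                (g["pos0"].to_numpy() >= p.region.start)
                & (g["pos0"].to_numpy() < p.region.end)
                & (g["context"] == p.context.value).to_numpy()
            )
            k = int(sel.sum())
            base = rng_m.uniform(0.02, 0.96 - p.delta, k)
            lo, hi = base, base + p.delta
            shifted = np.isin(pops, list(shifted_pops[p.comparison]))
            if p.direction == "increased":
                m_pop[np.ix_(sel, ~shifted)] = lo[:, None]
                m_pop[np.ix_(sel, shifted)] = hi[:, None]
            else:
                m_pop[np.ix_(sel, ~shifted)] = hi[:, None]
                m_pop[np.ix_(sel, shifted)] = lo[:, None]
        m_acc = np.clip(
            m_pop + rng_m.normal(0.0, cfg.accession_jitter_sd, m_pop.shape), 0.0, 1.0
        )
        for p in planted:
            if p.region.chrom != chrom:
                continue
            sel = (
                (g["pos0"].to_numpy() >= p.region.start)
                & (g["pos0"].to_numpy() < p.region.end)
                & (g["context"] == p.context.value).to_numpy()
            )
            planted_levels[p.dmr_index] = m_acc[sel].mean(axis=0)
        depth = np.maximum(rng_m.poisson(cfg.depth_mean, m_acc.shape), 1)
        n_meth = rng_m.binomial(depth, m_acc + (1.0 - m_acc) * eps)
        for k, aid in enumerate(acc_ids):
            methylomes[aid].append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos0": g["pos0"].to_numpy(),
                        "strand": g["strand"].to_numpy(),
                        "context": g["context"].to_numpy(),
                        "n_meth": n_meth[:, k],
                        "n_unmeth": depth[:, k] - n_meth[:, k],
                    }
                )
            )
    methylomes = {
        aid: MethylomeTable(pd.concat(parts, ignore_index=True), accession=aid)
        for aid, parts in methylomes.items()
    }

    # --- chloroplast control per accession -------------------------------
    rng_c = streams["chloroplast"]
    chloroplast = {
        aid: simulate_chloroplast_control(eps, cfg.depth_mean, 10_000, rng_c, accession=aid)
        for aid in acc_ids
    }

    # --- SNP genotypes ----------------------------------------------------
    rng_s = streams["snps"]
    mv_regions = [
        p.region for p in planted if p.delta > 0.4  # high methylation-variation windows
    ]
    chroms_l, pos_l, dos_rows = [], [], []
    scale = np.array([cfg.pi_scale[p] for p in pops])
    for chrom, length in cfg.genome:
        n_bg = rng_s.poisson(length * cfg.snp_per_kb / 1000.0)
        positions = list(rng_s.choice(length, size=min(n_bg, length), replace=False))
        for reg in mv_regions:
            if reg.chrom != chrom:
                continue
            extra = rng_s.poisson(len(reg) * cfg.snp_per_kb / 1000.0 * (cfg.mv_mutation_multiplier - 1.0))
            positions.extend(rng_s.integers(reg.start, reg.end, size=extra).tolist())
        positions = np.unique(np.asarray(positions, dtype=np.int64))
        q0 = rng_s.uniform(0.1, 0.5, len(positions))
        qpop = np.minimum(q0[:, None] * scale[None, :], 0.5)  # (n_sites, n_acc)
        dos = 2.0 * (rng_s.random(qpop.shape) < qpop)
        chroms_l.extend([chrom] * len(positions))
        pos_l.extend(positions.tolist())
        dos_rows.append(dos)

    dosages = np.vstack(dos_rows).T if dos_rows else np.empty((n_acc, 0))
    chrom_arr = np.array(chroms_l, dtype=object)
    pos_arr = np.array(pos_l, dtype=np.int64)

    # --- association planting --------------------------------------------
    rng_t = streams["te"]
    rng_si = streams["sirna"]
    associations: list[PlantedAssociation] = []
    sirna_rows: list[dict] = []
    te_rows: list[dict] = []
    extra_snp = []  # (chrom, pos, dosage_vector, assoc)
    genome_len = dict(cfg.genome)
    for p in planted:
        x = planted_levels[p.dmr_index]
        if rng_si.random() < cfg.fraction_dmrs_with.get("sirna", 0.0):
            rpm = correlated_rpm(x, cfg.association_r, rng_si)
            cid = f"sir_dmr{p.dmr_index}"
            start = max(0, p.region.start - 50)
            sirna_rows.append(
                {"chrom": p.region.chrom, "start": start, "end": p.region.end + 50, "id": cid}
                | dict(zip(acc_ids, rpm))
            )
            associations.append(PlantedAssociation(p.dmr_index, "sirna", cid, cfg.association_r, 0))
        if rng_t.random() < cfg.fraction_dmrs_with.get("te", 0.0):
            dist = int(rng_t.integers(0, cfg.te_plant_max_dist))
            r_eff = cfg.association_r * max(0.0, 1.0 - dist / cfg.te_decay_span)
            pres = correlated_presence(x, r_eff, rng_t)
            pos = min(p.region.end + dist, genome_len[p.region.chrom] - 1)
            tid = f"tev_dmr{p.dmr_index}"
            te_rows.append(
                {"chrom": p.region.chrom, "start": pos, "end": pos + 1, "id": tid}
                | dict(zip(acc_ids, pres))
            )
            associations.append(PlantedAssociation(p.dmr_index, "te", tid, r_eff, dist))
        if rng_s.random() < cfg.fraction_dmrs_with.get("snp", 0.0):
            dist = int(rng_s.integers(0, cfg.snp_plant_max_dist))
            pos = min(p.region.end + dist, genome_len[p.region.chrom] - 1)
            dos_vec = 2.0 * correlated_presence(x, cfg.association_r, rng_s)
            extra_snp.append((p.region.chrom, pos, dos_vec))
            associations.append(
                PlantedAssociation(p.dmr_index, "snp", f"{p.region.chrom}:{pos}", cfg.association_r, dist)
            )

    if extra_snp:
        for chrom, pos, vec in extra_snp:
            chrom_arr = np.append(chrom_arr, chrom)
            pos_arr = np.append(pos_arr, pos)
            dosages = np.hstack([dosages, vec[:, None]])
        order = np.lexsort((pos_arr, chrom_arr.astype(str)))
        chrom_arr, pos_arr, dosages = chrom_arr[order], pos_arr[order], dosages[:, order]

    genotypes = GenotypeMatrix(
        accessions=list(acc_ids),
        chroms=chrom_arr,
        pos0=pos_arr,
        ref=np.array(["A"] * len(pos_arr), dtype=object),
        alt=np.array(["G"] * len(pos_arr), dtype=object),
        dosages=dosages,
    )

    # --- background siRNA clusters and TE variants ------------------------
    for chrom, length in cfg.genome:
        for start in range(0, length - 1000, cfg.sirna_bg_every_bp):
            s = start + int(rng_si.integers(0, 2000))
            e = s + int(rng_si.integers(200, 1000))
            if e >= length:
                continue
            rpm = np.maximum(rng_si.lognormal(3.0, 1.0, n_acc), 0.0)
            sirna_rows.append(
                {"chrom": chrom, "start": s, "end": e, "id": f"sir_{chrom}_{s}"}
                | dict(zip(acc_ids, rpm))
            )
        for start in range(0, length - 100, cfg.te_bg_every_bp):
            pos = start + int(rng_t.integers(0, 5000))
            if pos >= length:
                continue
            pres = (rng_t.random(n_acc) < rng_t.uniform(0.2, 0.8)).astype(float)
            te_rows.append(
                {"chrom": chrom, "start": pos, "end": pos + 1, "id": f"tev_{chrom}_{pos}"}
                | dict(zip(acc_ids, pres))
            )
    sirna = pd.DataFrame(sirna_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    te_variants = pd.DataFrame(te_rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    # --- annotation: genes, exons, TE mask --------------------------------
    rng_a = streams["annotation"]
    gene_rows = []
    te_bed_rows = []
    gid = 0
    for chrom, length in cfg.genome:
        for start in range(500, length - 4000, cfg.gene_every_bp):
            gid += 1
            gstart = start + int(rng_a.integers(0, 1500))
            glen = int(rng_a.integers(2000, 4000))
            gend = min(gstart + glen, length - 1)
            e1 = (gstart, gstart + int(0.3 * (gend - gstart)))
            e2 = (gstart + int(0.6 * (gend - gstart)), gend)
            gene_rows.append(
                {
                    "gene_id": f"gene{gid:05d}",
                    "chrom": chrom,
                    "start": gstart,
                    "end": gend,
                    "exons": f"{e1[0]}-{e1[1]};{e2[0]}-{e2[1]}",
                }
            )
        pos = 0
        while pos < length - 6000:
            pos += int(rng_a.integers(1000, 6000))
            te_len = int(rng_a.integers(500, 5000))
            if pos + te_len < length:
                te_bed_rows.append({"chrom": chrom, "start": pos, "end": pos + te_len})
            pos += te_len
    genes = pd.DataFrame(gene_rows)
    te_bed = pd.DataFrame(te_bed_rows)

    # --- expression (null: independent of methylation) ---------------------
    rng_e = streams["expression"]
    expression = pd.DataFrame(
        rng_e.lognormal(2.0, 1.0, (len(genes), n_acc)),
        index=pd.Index(genes["gene_id"], name="id"),
        columns=acc_ids,
    )

    # --- DSRs --------------------------------------------------------------
    rng_d = streams["dsr"]
    dsr = []
    for chrom, length in cfg.genome:
        for _ in range(cfg.n_dsr_per_chrom):
            dlen = int(rng_d.integers(cfg.dsr_length // 2, cfg.dsr_length * 3 // 2))
            s = int(rng_d.integers(0, max(1, length - dlen)))
            dsr.append(GenomicRegion(chrom, s, s + dlen))

    # --- term map -----------------------------------------------------------
    rng_g = streams["terms"]
    term_rows = []
    for g in genes["gene_id"]:
        for t in rng_g.choice(cfg.n_terms, size=rng_g.integers(1, 4), replace=False):
            term_rows.append({"gene": g, "term": f"T{t:03d}", "term_name": f"term {t}"})
    terms = pd.DataFrame(term_rows)

    # --- null regions (guaranteed DMR-free) ---------------------------------
    null_regions = []
    for chrom, length in cfg.genome:
        step = max(length // (2 * max(len(planted), 1) + 4), 2000)
        for s in range(1000, length - 1000, step):
            reg = GenomicRegion(chrom, s, s + 1000)
            padded = GenomicRegion(chrom, max(0, s - 2000), s + 3000)
            if not any(padded.overlaps(p.region) for p in planted):
                null_regions.append(reg)
    truth = TruthSet(planted, associations, null_regions)

    ds = SimulatedDataset(
        config=cfg,
        panel=panel,
        methylomes=methylomes,
        chloroplast=chloroplast,
        genotypes=genotypes,
        sirna=sirna,
        te_variants=te_variants,
        expression=expression,
        genes=genes,
        te_bed=te_bed,
        dsr=dsr,
        terms=terms,
        planted_levels=planted_levels,
    )
    if out_dir is not None:
        write_dataset(ds, truth, out_dir)
    return ds, truth


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def genes_to_gff3(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            fh.write(
                f"{r.chrom}\tsim\tgene\t{r.start + 1}\t{r.end}\t.\t+\t.\tID={r.gene_id}\n"
            )
            for i, span in enumerate(r.exons.split(";")):
                s, e = span.split("-")
                fh.write(
                    f"{r.chrom}\tsim\texon\t{int(s) + 1}\t{e}\t.\t+\t.\t"
                    f"ID={r.gene_id}.exon{i + 1};Parent={r.gene_id}\n"
                )


def write_dataset(ds: SimulatedDataset, truth: TruthSet, out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    (out / "meth").mkdir(parents=True, exist_ok=True)
    (out / "chloroplast").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    iof.write_panel(ds.panel, out / "panel.tsv")
    pd.DataFrame(ds.config.genome, columns=["chrom", "length"]).to_csv(
        out / "genome.tsv", sep="\t", index=False
    )
    for aid, m in ds.methylomes.items():
        iof.write_cytosine_report(m, out / "meth" / f"{aid}.cov.tsv")
    for aid, m in ds.chloroplast.items():
        iof.write_cytosine_report(m, out / "chloroplast" / f"{aid}.cp.tsv")
    iof.write_vcf(ds.genotypes, out / "snps.vcf")
    iof.write_coord_matrix(ds.sirna, out / "sirna.tsv")
    iof.write_coord_matrix(ds.te_variants, out / "te_variants.tsv")
    iof.write_matrix(ds.expression, out / "expression.tsv")
    genes_to_gff3(ds.genes, out / "genes.gff3")
    ds.te_bed.to_csv(out / "te.bed", sep="\t", index=False, header=False)
    with open(out / "dsr.bed", "w") as fh:
        for r in ds.dsr:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    ds.terms.to_csv(out / "terms.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "dmr_index": p.dmr_index,
                "chrom": p.region.chrom,
                "start": p.region.start,
                "end": p.region.end,
                "context": p.context.value,
                "comparison": p.comparison.value,
                "direction": p.direction,
                "delta": p.delta,
            }
            for p in truth.planted_dmrs
        ]
    ).to_csv(out / "truth" / "planted_dmrs.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(a) for a in truth.planted_associations]).to_csv(
        out / "truth" / "planted_associations.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end} for r in truth.null_regions]
    ).to_csv(out / "truth" / "null_regions.tsv", sep="\t", index=False)
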