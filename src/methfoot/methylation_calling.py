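"""Per-cytosine methylation-state calling against a non-conversion null.

Bisulfite conversion is imperfect: a fraction epsilon of truly
unmethylated cytosines escapes conversion and reads as methylated.
epsilon is estimated per library from the naturally unmethylated
chloroplast genome; a site is called methylated when its methylated read
count is improbably high under Binomial(depth, epsilon), after
Benjamini-Hochberg correction across all tested sites of the library
(all contexts jointly, FDR < 0.01).  Libraries with epsilon >= 1% fail QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MethylomeTable
from .types import Context, GenomicRegion

logger = logging.getLogger("methfoot")

QC_MAX_NONCONVERSION = 0.01
DEFAULT_MIN_DEPTH = 4
SITE_FDR = 0.01


@dataclass(frozen=True)
class NonConversionEstimate:
    rate: float
    n_sites: int
    n_reads: int

    @property
    def passes_qc(self) -> bool:
        return self.rate < QC_MAX_NONCONVERSION


def estimate_nonconversion(chloroplast: MethylomeTable) -> NonConversionEstimate:
    """Pooled methylated-read fraction over all chloroplast cytosines."""
    n_meth = int(chloroplast.df["n_meth"].sum())
    n_reads = int(n_meth + chloroplast.df["n_unmeth"].sum())
    if n_reads == 0:
        raise ValueError("chloroplast control has zero total reads")
    return NonConversionEstimate(
        rate=n_meth / n_reads, n_sites=len(chloroplast), n_reads=n_reads
    )


def call_site_states(
    methylome: MethylomeTable,
    eps: NonConversionEstimate | float,
    min_depth: int = DEFAULT_MIN_DEPTH,
    force: bool = False,
) -> pd.DataFrame:
    """Binomial-test every sufficiently covered cytosine of one accession.

    Returns the methylome table with added columns p_value, q_value and
    status in {methylated, unmethylated, low_depth}.  Sites with depth
    below `min_depth` are excluded from testing; BH runs across the
    remaining sites of all contexts jointly.
    """
    rate = eps.rate if isinstance(eps, NonConversionEstimate) else float(eps)
    if isinstance(eps, NonConversionEstimate) and not eps.passes_qc:
        msg = f"library fails non-conversion QC (eps={eps.rate:.4f} >= 1%)"
        if not force:
            logger.warning("%s; proceeding (pass force=True to silence)", msg)

    df = methylome.df.copy()
    depth = (df["n_meth"] + df["n_unmeth"]).to_numpy()
    n_meth = df["n_meth"].to_numpy()
    tested = depth >= min_depth

    p = np.full(len(df), np.nan)
    if tested.any():
        if rate == 0.0:
            # degenerate null: any methylated read is "impossible"
            pt = np.where(n_meth[tested] > 0, 0.0, 1.0)
            if (pt == 0).any():
                logger.warning(
                    "eps=0 with methylated reads: p clamped to smallest float"
                )
                pt = np.where(pt == 0.0, np.nextafter(0.0, 1.0), pt)
        else:
            # upper tail P(X >= n_meth) under Binomial(depth, eps)
            pt = stats.binom.sf(n_meth[tested] - 1, depth[tested], rate)
        p[tested] = pt

    q = np.full(len(df), np.nan)
    if tested.any():
        _, q_adj, _, _ = multipletests(p[tested], method="fdr_bh")
        q[tested] = q_adj

    status = np.where(tested, np.where(q < SITE_FDR, "methylated", "unmethylated"), "low_depth")
    df["p_value"] = p
    df["q_value"] = q
    df["status"] = status
    return df


@dataclass
class RegionMethylation:
    region: GenomicRegion
    context: Context
    accession: str
    level: float | None  # None when no qualifying site (missing, not 0)
    n_sites_covered: int


def weighted_methylation(
    methylome: MethylomeTable,
    region: GenomicRegion,
    context: Context | str,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> RegionMethylation:
    """Weighted methylation level of a region for one accession.

    Sum of methylated reads over sum of total reads across the region's
    context sites with depth >= min_depth; missing when no site qualifies.
    """
    context = Context(context)
    df = methylome.subset(chrom=region.chrom, context=context)
    inside = df[(df["pos0"] >= region.start) & (df["pos0"] < region.end)]
    depth = inside["n_meth"] + inside["n_unmeth"]
    ok = inside[depth >= min_depth]
    total = int((ok["n_meth"] + ok["n_unmeth"]).sum())
    if total == 0:
        return RegionMethylation(region, context, methylome.accession, None, 0)
    level = float(ok["n_meth"].sum()) / total
    return RegionMethylation(region, context, methylome.accession, level, len(ok))


def genome_methylation_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-context counts of tested and methylated sites (Table S4-style)."""
    tested = calls[calls["status"] != "low_depth"]
    out = (
        tested.groupby("context")
        .agg(
            n_tested=("status", "size"),
            n_methylated=("status", lambda s: int((s == "methylated").sum())),
        )
        .reset_index()
    )
    out["fraction_methylated"] = out["n_methylated"] / out["n_tested"]
    return out
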