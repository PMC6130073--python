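"""DMR classification: context overlap, process overlap, genomic composition.

CG- and CHG-DMRs from one comparison are split into unique (u-CG, u-CHG)
and overlapping (o-CG/CHG) classes by >= 1 bp interval overlap; CHH-DMRs
are never relabelled.  Composition assigns each region to TE / exon /
intron / intergenic by majority bp with precedence TE > exon > intron
(the TE mask supersedes gene annotation).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationSet
from .types import DMR, GenomicRegion

logger = logging.getLogger("methfoot")

COMPOSITION_PRECEDENCE = ["TE", "exon", "intron", "intergenic"]


def _region(x) -> GenomicRegion:
    return x.region if isinstance(x, DMR) else x


def classify_context_overlap(
    cg: list[DMR], chg: list[DMR], chh: list[DMR], min_overlap_bp: int = 1
) -> tuple[pd.DataFrame, list[tuple[DMR, DMR]]]:
    """Label CG/CHG DMRs unique vs overlapping; CHH passes through.

    Returns a per-DMR label table and the list of overlapping
    (CG, CHG) pairs.
    """
    pairs = [
        (a, b)
        for a in cg
        for b in chg
        if a.region.overlap_bp(b.region) >= min_overlap_bp
    ]
    over_cg = {id(a) for a, _ in pairs}
    over_chg = {id(b) for _, b in pairs}
    rows = []
    for d in cg:
        rows.append(_label_row(d, "o-CG/CHG" if id(d) in over_cg else "u-CG"))
    for d in chg:
        rows.append(_label_row(d, "o-CG/CHG" if id(d) in over_chg else "u-CHG"))
    for d in chh:
        rows.append(_label_row(d, "CHH"))
    return pd.DataFrame(rows), pairs


def _label_row(d: DMR, label: str) -> dict:
    return {
        "dmr_id": d.dmr_id,
        "chrom": d.region.chrom,
        "start": d.region.start,
        "end": d.region.end,
        "context": d.context.value,
        "comparison": d.comparison.value,
        "context_class": label,
    }


def assign_composition(
    region: GenomicRegion, ann: AnnotationSet
) -> tuple[str, dict[str, int]]:
    """Majority-bp composition with TE > exon > intron > intergenic precedence.

    The bp breakdown sums exactly to the region length; ties go to the
    higher-precedence category.
    """
    bp = ann.category_bp(region)
    best = max(COMPOSITION_PRECEDENCE, key=lambda c: (bp[c], -COMPOSITION_PRECEDENCE.index(c)))
    return best, bp


def compare_length_distributions(
    sets: dict[str, list], min_members: int = 2
) -> tuple[pd.DataFrame, float | None, pd.DataFrame]:
    """Summaries plus one-way ANOVA and pairwise t-tests on region lengths."""
    lengths = {}
    for name, regions in sets.items():
        vals = np.array([len(_region(r)) for r in regions], dtype=float)
        if len(vals) < min_members:
            logger.warning("length comparison: set %r has < %d members, excluded", name, min_members)
            continue
        lengths[name] = vals
    summary = pd.DataFrame(
        [
            {"set": k, "n": len(v), "mean_bp": float(v.mean()), "median_bp": float(np.median(v))}
            for k, v in lengths.items()
        ]
    )
    anova_p = None
    pairwise_rows = []
    if len(lengths) >= 2:
        anova_p = float(stats.f_oneway(*lengths.values()).pvalue)
        for a, b in combinations(lengths, 2):
            p = float(stats.ttest_ind(lengths[a], lengths[b], equal_var=False).pvalue)
            pairwise_rows.append({"set_a": a, "set_b": b, "p": p})
    return summary, anova_p, pd.DataFrame(pairwise_rows)


def overlap_processes(
    dos: list[DMR], imp: list[DMR], min_overlap_bp: int = 1
) -> pd.DataFrame:
    """Shared/unique DMR counts per context, each side counted separately.

    A Dos DMR spanning two Imp DMRs counts once as shared on the Dos
    side and twice on the Imp side.
    """
    rows = []
    contexts = sorted({d.context.value for d in dos} | {d.context.value for d in imp})
    for ctx in contexts:
        dd = [d for d in dos if d.context.value == ctx]
        ii = [d for d in imp if d.context.value == ctx]
        dos_shared = sum(
            1 for d in dd if any(d.region.overlap_bp(i.region) >= min_overlap_bp for i in ii)
        )
        imp_shared = sum(
            1 for i in ii if any(i.region.overlap_bp(d.region) >= min_overlap_bp for d in dd)
        )
        rows.append(
            {
                "context": ctx,
                "n_dos": len(dd),
                "n_imp": len(ii),
                "dos_shared": dos_shared,
                "dos_unique": len(dd) - dos_shared,
                "imp_shared": imp_shared,
                "imp_unique": len(ii) - imp_shared,
            }
        )
    return pd.DataFrame(rows)
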