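"""End-to-end orchestration of the synthetic-panel analysis.

run_all simulates a panel, estimates non-conversion rates, calls site
states, detects DMRs for both processes and all contexts, classifies
them, runs the diversity stratifications, the local association study,
pure-DMR derivation, enrichment and the expression correlation, writing
every layer under the output directory.  With a fixed config seed the
output tree is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    dmr_detection,
    dmr_landscape,
    diversity,
    enrichment as enrichment_mod,
    io_formats as iof,
    local_association as assoc,
    methylation_calling as calling,
    synthetic_data,
)
from ._intervals import IntervalSet
from .types import COMPARISON_GROUPS, Comparison, Context, GenomicRegion

logger = logging.getLogger("methfoot")


def annotation_from_dataset(ds: synthetic_data.SimulatedDataset) -> iof.AnnotationSet:
    """Build the composition index directly from simulated tables."""
    genes = {
        r.gene_id: GenomicRegion(r.chrom, int(r.start), int(r.end))
        for r in ds.genes.itertuples(index=False)
    }
    ann = iof.AnnotationSet(genes=genes, chrom_lengths=dict(ds.config.genome))
    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    gene_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in ds.genes.itertuples(index=False):
        gene_by_chrom.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
        for span in r.exons.split(";"):
            s, e = span.split("-")
            exon_by_chrom.setdefault(r.chrom, []).append((int(s), int(e)))
    te_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in ds.te_bed.itertuples(index=False):
        te_by_chrom.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    for chrom, _ in ds.config.genome:
        te = iof._iset(te_by_chrom.get(chrom, []))
        exon = iof._iset(exon_by_chrom.get(chrom, []))
        gene_cov = iof._iset(gene_by_chrom.get(chrom, []))
        ann.te[chrom] = te
        ann.exon[chrom] = exon.subtract(te)
        ann.intron[chrom] = gene_cov.subtract(exon).subtract(te)
    return ann


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float) + "\n")


def run_all(
    config: synthetic_data.SimulationConfig,
    out_dir: str,
    n_perm: int = assoc.N_PERM,
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = synthetic_data.simulate_panel(config, out / "data")
    panel = ds.panel
    summary: dict = {"seed": config.seed}

    # --- non-conversion QC and site calling -------------------------------
    eps_rows = []
    call_summaries = []
    for aid in [a.id for a in panel]:
        est = calling.estimate_nonconversion(ds.chloroplast[aid])
        eps_rows.append(
            {"accession": aid, "epsilon": est.rate, "n_reads": est.n_reads, "passes_qc": est.passes_qc}
        )
        calls = calling.call_site_states(ds.methylomes[aid], est)
        s = calling.genome_methylation_summary(calls)
        s.insert(0, "accession", aid)
        call_summaries.append(s)
    pd.DataFrame(eps_rows).to_csv(out / "nonconversion.tsv", sep="\t", index=False)
    pd.concat(call_summaries, ignore_index=True).to_csv(
        out / "site_calls_summary.tsv", sep="\t", index=False
    )

    # --- DMR detection ------------------------------------------------------
    all_dmrs = []
    by_combo: dict[str, list] = {}
    for cmp in Comparison:
        for ctx in config.contexts:
            dmrs = dmr_detection.call_dmrs(ds.methylomes, panel, cmp, ctx)
            by_combo[f"{cmp.value}_{ctx}"] = dmrs
            all_dmrs.extend(dmrs)
            iof.write_regions_bed(dmrs, out / f"dmrs_{cmp.value}_{ctx}.bed")
    summary["n_dmrs"] = {k: len(v) for k, v in by_combo.items()}

    # --- landscape ------------------------------------------------------------
    ann = annotation_from_dataset(ds)
    label_frames = []
    for cmp in Comparison:
        labels, pairs = dmr_landscape.classify_context_overlap(
            by_combo.get(f"{cmp.value}_CG", []),
            by_combo.get(f"{cmp.value}_CHG", []),
            by_combo.get(f"{cmp.value}_CHH", []),
        )
        if len(labels):
            labels["n_o_pairs"] = len(pairs)
            label_frames.append(labels)
    labels = (
        pd.concat(label_frames, ignore_index=True)
        if label_frames
        else pd.DataFrame(columns=["dmr_id", "context_class"])
    )
    if len(labels):
        comp_rows = []
        for d in all_dmrs:
            c, bp = dmr_landscape.assign_composition(d.region, ann)
            comp_rows.append({"dmr_id": d.dmr_id, "composition": c, **{f"bp_{k}": v for k, v in bp.items()}})
        labels = labels.merge(pd.DataFrame(comp_rows), on="dmr_id", how="left")
    labels.to_csv(out / "dmr_labels.tsv", sep="\t", index=False)

    length_summary, anova_p, pairwise = dmr_landscape.compare_length_distributions(
        {"DMR": [d.region for d in all_dmrs], "DSR": ds.dsr}
    )
    length_summary.to_csv(out / "length_comparison.tsv", sep="\t", index=False)
    proc = dmr_landscape.overlap_processes(
        [d for d in all_dmrs if d.comparison == Comparison.DOS],
        [d for d in all_dmrs if d.comparison == Comparison.IMP],
    )
    proc.to_csv(out / "process_overlap.tsv", sep="\t", index=False)

    # --- diversity --------------------------------------------------------------
    dmr_regions = [d.region for d in all_dmrs]
    strat, strat_anova = diversity.stratified_pi_comparison(
        ds.genotypes, dmr_regions, ds.dsr, ann
    )
    strat.to_csv(out / "pi_stratified.tsv", sep="\t", index=False)
    pi_regions = dmr_regions if dmr_regions else truth.null_regions
    pop_pi, pop_pi_tests = diversity.per_population_pi(ds.genotypes, panel, pi_regions)
    pop_pi.to_csv(out / "pi_per_population.tsv", sep="\t", index=False)
    pop_pi_tests.to_csv(out / "pi_per_population_tests.tsv", sep="\t", index=False)
    windows, win_cmp = diversity.methylation_variation_windows(
        ds.methylomes,
        panel,
        *COMPARISON_GROUPS[Comparison.DOS],
        genome=config.genome,
        g=ds.genotypes,
        context=Context.CG,
        ann=ann,
    )
    windows.to_csv(out / "mv_windows.tsv", sep="\t", index=False)
    corr = diversity.dmr_level_pi_correlation(ds.genotypes, all_dmrs, panel)
    _json_dump(
        {"anova_by_composition": strat_anova, "mv_window_ttest": win_cmp,
         "length_anova_p": anova_p, "dmr_level_pi_correlation": corr},
        out / "diversity_summary.json",
    )

    # --- local association -------------------------------------------------------
    engine = assoc.PermutationEngine(n_perm=n_perm, seed=config.seed)
    results: list[assoc.AssociationResult] = []
    if all_dmrs:
        levels = assoc.dmr_level_matrix(all_dmrs, ds.methylomes)
        results += assoc.associate_sirna(all_dmrs, levels, ds.sirna, engine=engine)
        te_res = assoc.associate_te(all_dmrs, levels, ds.te_variants, engine=engine)
        results += te_res
        results += assoc.associate_snp(all_dmrs, levels, ds.genotypes, engine=engine)
        assoc.te_distance_bins(te_res).to_csv(out / "te_distance_bins.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "dmr_id": r.dmr_id, "factor_type": r.factor_type, "factor_id": r.factor_id,
                "r": r.r, "n_perm_exceed": r.n_perm_exceed, "significant": r.significant,
                "distance": r.distance,
            }
            for r in results
        ]
    ).to_csv(out / "associations.tsv", sep="\t", index=False)
    pure, assoc_summary = assoc.pure_dmrs(results, all_dmrs)
    iof.write_regions_bed(pure, out / "pure_dmrs.bed")
    summary["association"] = assoc_summary

    # --- enrichment and expression -------------------------------------------------
    background = list(ds.genes["gene_id"])
    pure_genes = sorted({g for d in pure for g in ann.genes_overlapping(d.region)})
    if pure_genes:
        enr = enrichment_mod.fisher_enrichment(pure_genes, background, ds.terms)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["n_enriched_terms"] = int(enr["significant"].sum()) if len(enr) else 0
        gene_to_dmr = {}
        for d in pure:
            for gid in ann.genes_overlapping(d.region):
                gene_to_dmr.setdefault(gid, d.dmr_id)
        expr_corr = assoc.correlate_expression(gene_to_dmr, ds.expression, assoc.dmr_level_matrix(pure, ds.methylomes))
        expr_corr.to_csv(out / "expression_correlation.tsv", sep="\t", index=False)
    summary["n_pure_dmrs"] = len(pure)
    _json_dump(summary, out / "summary.json")
    return summary
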