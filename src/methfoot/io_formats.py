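"""Readers and writers for every external format the pipeline touches.

Dialect rules: the cytosine report and VCF are 1-based on disk and are
converted to 0-based half-open coordinates on read; BED and all internal
tables are 0-based half-open throughout.  Round-trip identity with the
matching writer is part of each reader's contract.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import IntervalSet
from .types import Accession, Comparison, Context, DMR, GenomicRegion, Population

logger = logging.getLogger("methfoot")

_CONTEXTS = {c.value for c in Context}

CYTOSINE_REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "n_meth",
    "n_unmeth",
    "context",
    "tri",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# methylome tables (Bismark-style cytosine report)
# ---------------------------------------------------------------------------


class MethylomeTable:
    """Per-cytosine counts for one accession/library.

    Backed by a DataFrame with columns chrom, pos0, strand, context,
    n_meth, n_unmeth, sorted by (chrom, pos0).  `pos0` is 0-based.
    """

    def __init__(self, df: pd.DataFrame, accession: str = ""):
        required = {"chrom", "pos0", "strand", "context", "n_meth", "n_unmeth"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"MethylomeTable missing columns: {sorted(missing)}")
        if len(df) and ((df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any()):
            raise ValueError("negative read counts")
        bad = set(df["context"].unique()) - _CONTEXTS
        if bad:
            raise ValueError(f"unknown contexts: {sorted(bad)}")
        cols = ["chrom", "pos0", "strand", "context", "n_meth", "n_unmeth"]
        self.df = (
            df[cols].sort_values(["chrom", "pos0"], kind="stable").reset_index(drop=True)
        )
        self.accession = accession

    def __len__(self) -> int:
        return len(self.df)

    @property
    def depth(self) -> np.ndarray:
        return (self.df["n_meth"] + self.df["n_unmeth"]).to_numpy()

    def subset(self, chrom: str | None = None, context: Context | str | None = None) -> pd.DataFrame:
        df = self.df
        if chrom is not None:
            df = df[df["chrom"] == chrom]
        if context is not None:
            df = df[df["context"] == Context(context).value]
        return df

    def merge_cg_strands(self) -> "MethylomeTable":
        """Collapse symmetric CpG pairs (+ at p, - at p+1) into one + site.

        Off by default in the pipeline (`merge_cg_strands` config flag);
        non-CG sites pass through untouched.
        """
        df = self.df
        cg = df[df["context"] == "CG"].copy()
        other = df[df["context"] != "CG"]
        # the minus-strand member of a pair reports at pos0 of the G; map to C
        key = cg["pos0"].where(cg["strand"] == "+", cg["pos0"] - 1)
        cg["_key"] = key
        agg = (
            cg.groupby(["chrom", "_key"], as_index=False)
            .agg(n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum"))
            .rename(columns={"_key": "pos0"})
        )
        agg["strand"] = "+"
        agg["context"] = "CG"
        merged = pd.concat([agg, other], ignore_index=True)
        return MethylomeTable(merged, accession=self.accession)


def parse_cytosine_report(path: str | os.PathLike, accession: str = "") -> MethylomeTable:
    """Read a Bismark-style cytosine report (TSV, 1-based positions).

    Columns: chrom, pos, strand, count_methylated, count_unmethylated,
    context, trinucleotide.  The trinucleotide column is ignored.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CYTOSINE_REPORT_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "tri": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CYTOSINE_REPORT_COLUMNS)
    if not len(df):
        logger.warning("empty cytosine report: %s", path)
    for col in ("pos", "n_meth", "n_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() if len(df) else pd.Series(dtype=bool)
        if len(df) and bad.any():
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"{path}: malformed {col!r} field at line {lineno}")
        df[col] = vals.astype(np.int64) if len(df) else vals
    if len(df):
        neg = (df["n_meth"] < 0) | (df["n_unmeth"] < 0)
        if neg.any():
            lineno = int(np.flatnonzero(neg.to_numpy())[0]) + 1
            raise ParseError(f"{path}: negative read count at line {lineno}")
        bad_ctx = ~df["context"].isin(_CONTEXTS)
        if bad_ctx.any():
            lineno = int(np.flatnonzero(bad_ctx.to_numpy())[0]) + 1
            tok = df["context"].iloc[lineno - 1]
            raise ParseError(f"{path}: unknown context {tok!r} at line {lineno}")
    out = df.drop(columns=["tri"]).rename(columns={"pos": "pos0"})
    if len(out):
        out["pos0"] = out["pos0"] - 1  # 1-based dialect -> internal 0-based
    return MethylomeTable(out, accession=accession)


def write_cytosine_report(table: MethylomeTable, path: str | os.PathLike) -> None:
    df = table.df.copy()
    df["pos"] = df["pos0"] + 1
    df["tri"] = df["context"]
    df[CYTOSINE_REPORT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# accession panel
# ---------------------------------------------------------------------------


def read_panel(path: str | os.PathLike) -> list[Accession]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession", "population"} <= set(df.columns):
        raise ParseError(f"{path}: panel needs 'accession' and 'population' columns")
    panel = [Accession(r.accession, Population(r.population)) for r in df.itertuples()]
    ids = [a.id for a in panel]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate accession ids")
    return panel


def write_panel(panel: list[Accession], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"accession": [a.id for a in panel], "population": [a.population.value for a in panel]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes (VCF)
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (0/1/2, NaN missing) across a panel.

    dosages has shape (n_accessions, n_sites); sites are 0-based
    positions sorted within chromosome.
    """

    accessions: list[str]
    chroms: np.ndarray  # (n_sites,) str
    pos0: np.ndarray  # (n_sites,) int64
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray  # (n_acc, n_sites) float, NaN = missing
    n_skipped_multiallelic: int = 0

    def sites_in(self, region: GenomicRegion) -> np.ndarray:
        """Indices of sites inside a region."""
        on = self.chroms == region.chrom
        return np.flatnonzero(on & (self.pos0 >= region.start) & (self.pos0 < region.end))


def parse_genotypes(path: str | os.PathLike, panel: list[Accession] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Multi-allelic records are skipped with a counter; missing genotypes
    stay missing.  If a panel is given, VCF samples must cover it.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if panel is not None:
        missing = [a.id for a in panel if a.id not in samples]
        if missing:
            raise ParseError(f"{path}: panel accessions absent from VCF: {missing}")
    chroms, pos0, ref, alt, rows = [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = v.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        chroms.append(v.CHROM)
        pos0.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(dos)
    if n_multi:
        logger.warning("%s: skipped %d multi-allelic records", path, n_multi)
    dosages = (
        np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    )
    gm = GenotypeMatrix(
        accessions=samples,
        chroms=np.array(chroms, dtype=object),
        pos0=np.array(pos0, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosages=dosages,
        n_skipped_multiallelic=n_multi,
    )
    if panel is not None:
        order = [samples.index(a.id) for a in panel]
        gm.accessions = [a.id for a in panel]
        gm.dosages = gm.dosages[order]
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal homozygous-friendly VCF (GT only)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(gm.chroms)
        for c in chroms:
            maxp = int(gm.pos0[gm.chroms == c].max()) + 2 if len(gm.pos0) else 1
            fh.write(f"##contig=<ID={c},length={maxp}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accessions)
            + "\n"
        )
        for j in range(len(gm.pos0)):
            gts = "\t".join(
                code.get(float(d), "./.") if np.isfinite(d) else "./."
                for d in gm.dosages[:, j]
            )
            fh.write(
                f"{gm.chroms[j]}\t{gm.pos0[j] + 1}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# annotation (GFF3 genes + TE BED)
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Interval indexes for composition queries, per chromosome.

    Categories follow the precedence TE > exon > intron > intergenic:
    exon intervals have TE bp removed, intron intervals have TE and exon
    bp removed, so the three stored sets are mutually disjoint.
    """

    genes: dict[str, GenomicRegion]
    te: dict[str, IntervalSet] = field(default_factory=dict)
    exon: dict[str, IntervalSet] = field(default_factory=dict)
    intron: dict[str, IntervalSet] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def category_bp(self, region: GenomicRegion) -> dict[str, int]:
        """bp of the region in each category; sums exactly to len(region)."""
        if self.chrom_lengths and region.chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {region.chrom!r}")
        out = {}
        for name, sets in (("TE", self.te), ("exon", self.exon), ("intron", self.intron)):
            iset = sets.get(region.chrom)
            out[name] = iset.overlap_bp(region.start, region.end) if iset else 0
        out["intergenic"] = len(region) - out["TE"] - out["exon"] - out["intron"]
        return out

    def genes_overlapping(self, region: GenomicRegion) -> list[str]:
        return [g for g, r in self.genes.items() if r.overlaps(region)]


def parse_annotation(
    gff_path: str | os.PathLike,
    te_bed_path: str | os.PathLike,
    chrom_lengths: dict[str, int] | None = None,
) -> AnnotationSet:
    """Build the composition index from GFF3 gene models and a TE BED.

    Introns are gene spans minus exons; overlapping TEs are merged.  An
    exon outside its parent gene span is an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, GenomicRegion] = {}
    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    gene_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene in db.features_of_type("gene"):
        greg = GenomicRegion(gene.seqid, gene.start - 1, gene.end)
        genes[gene.id] = greg
        gene_by_chrom.setdefault(gene.seqid, []).append((greg.start, greg.end))
        for exon in db.children(gene, featuretype="exon"):
            if exon.start - 1 < greg.start or exon.end > greg.end:
                raise ParseError(
                    f"exon {exon.seqid}:{exon.start}-{exon.end} outside gene {gene.id}"
                )
            exon_by_chrom.setdefault(gene.seqid, []).append((exon.start - 1, exon.end))

    te_by_chrom: dict[str, list[tuple[int, int]]] = {}
    try:
        bed = pd.read_csv(te_bed_path, sep="\t", header=None, comment="#")
        for r in bed.itertuples(index=False):
            te_by_chrom.setdefault(str(r[0]), []).append((int(r[1]), int(r[2])))
    except pd.errors.EmptyDataError:
        pass

    ann = AnnotationSet(genes=genes, chrom_lengths=dict(chrom_lengths or {}))
    chroms = set(exon_by_chrom) | set(gene_by_chrom) | set(te_by_chrom) | set(
        ann.chrom_lengths
    )
    for c in chroms:
        te = _iset(te_by_chrom.get(c, []))
        exon_raw = _iset(exon_by_chrom.get(c, []))
        gene_raw = _iset(gene_by_chrom.get(c, []))
        intron_raw = gene_raw.subtract(exon_raw)
        ann.te[c] = te
        ann.exon[c] = exon_raw.subtract(te)
        ann.intron[c] = intron_raw.subtract(te)
    return ann


def _iset(pairs: list[tuple[int, int]]) -> IntervalSet:
    if not pairs:
        return IntervalSet.empty()
    s, e = zip(*pairs)
    return IntervalSet(np.array(s), np.array(e))


# ---------------------------------------------------------------------------
# region BED (DMRs and plain regions)
# ---------------------------------------------------------------------------

_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tcontext\tcomparison\t"
    "n_sites\tmean_a\tmean_b\tdiff\tp\tq\tdirection\n"
)


def write_regions_bed(regions: list, path: str | os.PathLike) -> None:
    """Write DMRs (or bare regions) as BED6+, 0-based half-open."""
    with open(path, "w") as fh:
        fh.write(_BED_HEADER)
        for x in regions:
            if isinstance(x, DMR):
                fh.write(
                    f"{x.region.chrom}\t{x.region.start}\t{x.region.end}\t{x.dmr_id}"
                    f"\t0\t.\t{x.context.value}\t{x.comparison.value}\t{x.n_sites}"
                    f"\t{x.mean_level_a!r}\t{x.mean_level_b!r}\t{x.diff!r}"
                    f"\t{x.p_value!r}\t{x.q_value!r}\t{x.direction}\n"
                )
            else:
                fh.write(
                    f"{x.chrom}\t{x.start}\t{x.end}\t.\t0\t.\t.\t.\t0\t0\t0\t0\t1\t1\t.\n"
                )


def read_regions_bed(path: str | os.PathLike) -> list:
    """Round-trip reader for write_regions_bed; plain rows come back as regions."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            region = GenomicRegion(f[0], int(f[1]), int(f[2]))
            if len(f) >= 15 and f[6] in _CONTEXTS:
                dmr = DMR(
                    region=region,
                    context=Context(f[6]),
                    comparison=Comparison(f[7]),
                    n_sites=int(f[8]),
                    mean_level_a=float(f[9]),
                    mean_level_b=float(f[10]),
                    diff=float(f[11]),
                    p_value=float(f[12]),
                    q_value=float(f[13]),
                    dmr_id=f[3],
                )
                out.append(dmr)
            else:
                out.append(region)
    return out


def read_bed_regions(path: str | os.PathLike) -> list[GenomicRegion]:
    """Plain >=3-column BED reader (e.g. previously published selected regions)."""
    out = []
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return out
    for r in df.itertuples(index=False):
        out.append(GenomicRegion(str(r[0]), int(r[1]), int(r[2])))
    return out


# ---------------------------------------------------------------------------
# coordinate matrices (siRNA RPM, TE variants) and plain matrices
# ---------------------------------------------------------------------------


def read_coord_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with chrom/start/end/id then one column per accession."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    need = {"chrom", "start", "end", "id"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(need)} + accessions")
    return df


def write_coord_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | os.PathLike, index_col: str = "id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t")
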