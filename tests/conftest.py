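import numpy as np
import pandas as pd
import pytest

from methfoot import synthetic_data as sd
from methfoot.io_formats import GenotypeMatrix, MethylomeTable
from methfoot.types import Accession, GenomicRegion, Population


def make_methylome(positions, n_meth, n_unmeth, context="CG", chrom="Chr1", accession=""):
    n = len(positions)
    return MethylomeTable(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos0": np.asarray(positions, dtype=np.int64),
                "strand": ["+"] * n,
                "context": [context] * n if isinstance(context, str) else list(context),
                "n_meth": np.asarray(n_meth, dtype=np.int64),
                "n_unmeth": np.asarray(n_unmeth, dtype=np.int64),
            }
        ),
        accession=accession,
    )


def make_genotypes(dosages, positions=None, chrom="Chr1", accessions=None):
    dosages = np.asarray(dosages, dtype=float)
    n_acc, n_sites = dosages.shape
    if positions is None:
        positions = np.arange(n_sites) * 10 + 5
    return GenotypeMatrix(
        accessions=accessions or [f"a{i}" for i in range(n_acc)],
        chroms=np.array([chrom] * n_sites, dtype=object),
        pos0=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        dosages=dosages,
    )


def reciprocal_overlap(a: GenomicRegion, b: GenomicRegion, frac: float = 0.5) -> bool:
    ov = a.overlap_bp(b)
    return ov >= frac * len(a) and ov >= frac * len(b)


@pytest.fixture(scope="session")
def small_panel_dataset():
    """One modest simulated panel reused by several test modules."""
    cfg = sd.SimulationConfig(
        seed=101,
        genome=[("Chr1", 600_000)],
        contexts=["CG", "CHG"],
        n_planted_dmrs={"Dos:CG": 5, "Dos:CHG": 3},
        fraction_dmrs_with={"sirna": 0.5, "te": 0.5, "snp": 0.5},
    )
    return sd.simulate_panel(cfg)


@pytest.fixture
def mini_panel():
    return [
        *[Accession(f"w{i}", Population.WILD) for i in range(3)],
        *[Accession(f"l{i}", Population.LANDRACE) for i in range(3)],
    ]
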