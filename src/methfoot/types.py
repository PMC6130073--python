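"""Core domain types shared across the pipeline.

All internal coordinates are 0-based half-open; 1-based file dialects
(cytosine report, VCF) are converted at the I/O boundary only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Population(str, enum.Enum):
    WILD = "wild"
    LANDRACE = "landrace"
    CULTIVAR = "cultivar"


class Context(str, enum.Enum):
    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"


class Comparison(str, enum.Enum):
    """Dos = domestication (wild vs landrace); Imp = improvement (landrace vs cultivar)."""

    DOS = "Dos"
    IMP = "Imp"


#: (group A, group B) per comparison; diff is defined as mean(B) - mean(A),
#: so "increased" means the selected (later) population gained methylation.
COMPARISON_GROUPS: dict[Comparison, tuple[Population, Population]] = {
    Comparison.DOS: (Population.WILD, Population.LANDRACE),
    Comparison.IMP: (Population.LANDRACE, Population.CULTIVAR),
}


@dataclass(frozen=True)
class Accession:
    id: str
    population: Population

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("accession id must be non-empty")
        object.__setattr__(self, "population", Population(self.population))


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} (start must be < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomicRegion") -> int | None:
        """Edge-to-edge distance in bp; 0 when overlapping; None across chroms."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.end <= self.start:
            return self.start - other.end
        return other.start - self.end


@dataclass
class DMR:
    """A differentially methylated region between two populations.

    diff = mean_level_B - mean_level_A where A is the earlier population
    (wild for Dos, landrace for Imp).  direction is "increased" iff the
    selected population gained methylation (diff > 0).
    """

    region: GenomicRegion
    context: Context
    comparison: Comparison
    n_sites: int
    mean_level_a: float
    mean_level_b: float
    diff: float
    p_value: float
    q_value: float
    direction: str = field(init=False)
    dmr_id: str = ""

    def __post_init__(self) -> None:
        self.direction = "increased" if self.diff > 0 else "decreased"
        if not self.dmr_id:
            self.dmr_id = (
                f"{self.comparison.value}_{self.context.value}_"
                f"{self.region.chrom}:{self.region.start}-{self.region.end}"
            )
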