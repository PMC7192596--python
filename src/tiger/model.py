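"""Domain types and coordinate conventions.

All genomic coordinates are 1-based and inclusive, following the
GenBank/BLAST convention.  An integrated element's span is
``[attL_start, attR_end]``, i.e. it includes both copies of the direct
repeat (DR) that flank the element.

Circular replicons are supported by allowing *internal* coordinates to
run past the replicon length (a feature or query window that wraps the
origin has ``end > length``); such coordinates are normalized modulo the
replicon length on output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Topology",
    "GeneClass",
    "SeedMode",
    "Replicon",
    "GeneFeature",
    "GenomeRecord",
    "SeedGene",
    "HmmHit",
    "INT_SEED_CLASSES",
    "RNA_CLASSES",
]


class Topology(str, enum.Enum):
    circular = "circular"
    linear = "linear"


class GeneClass(str, enum.Enum):
    """Functional gene classes relevant to element mapping.

    Y_INT:  tyrosine-family integrase (Phage_integrase domain).
    S_INT:  serine recombinase with the large C-terminal integrase domain
            (Resolvase + Recombinase domains).
    S_CORE: serine recombinase catalytic domain only (resolvase/invertase).
    DDE:    classical DDE transposase, used to seed IS-mode mapping.
    XER:    Xer chromosome-dimer resolvase (never an element seed).
    INTI:   integron integrase (never an element seed).
    """

    Y_INT = "Y-Int"
    S_INT = "S-Int"
    S_CORE = "S-Core"
    DDE = "DDE"
    XER = "Xer"
    INTI = "IntI"
    TRNA = "tRNA"
    TMRNA = "tmRNA"
    RRNA = "rRNA"
    OTHER_RNA = "other-RNA"
    CDS = "CDS"


#: classes eligible to seed element-mode (IGE) mapping
INT_SEED_CLASSES = frozenset({GeneClass.Y_INT, GeneClass.S_INT, GeneClass.S_CORE})

#: RNA gene classes used for target typing
RNA_CLASSES = frozenset(
    {GeneClass.TRNA, GeneClass.TMRNA, GeneClass.RRNA, GeneClass.OTHER_RNA}
)


class SeedMode(str, enum.Enum):
    IGE = "ige"
    IS = "is"


@dataclass
class Replicon:
    id: str
    seq: str
    topology: Topology = Topology.circular

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"replicon {self.id!r}: non-DNA characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Extract ``[start, end]`` (1-based inclusive), wrapping the origin
        on circular replicons; truncating at the ends of linear ones."""
        if start > end:
            raise ValueError(f"fetch: start {start} > end {end}")
        n = self.length
        if self.topology is Topology.linear:
            start = max(1, start)
            end = min(n, end)
            return self.seq[start - 1 : end]
        # circular: wrap via modular arithmetic
        out = []
        for i in range(start, end + 1):
            out.append(self.seq[(i - 1) % n])
        return "".join(out)

    def normalize(self, pos: int) -> int:
        """Map an internal (possibly >length or <1) coordinate onto [1, length]."""
        return (pos - 1) % self.length + 1


@dataclass
class GeneFeature:
    id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    klass: GeneClass = GeneClass.CDS
    top_pfam: Optional[tuple[str, float]] = None  # (name, bitscore)
    name: str = ""  # e.g. tRNA isotype "Arg", or gene symbol

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id!r}: strand must be + or -")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature {self.id!r}: invalid coordinates {self.start}..{self.end}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end

    def with_klass(self, klass: GeneClass) -> "GeneFeature":
        return replace(self, klass=klass)


@dataclass
class GenomeRecord:
    """A genome: a set of replicons plus typed gene features.

    ``genome_id`` follows the three-letter genus/species abbreviation plus
    serial number convention (e.g. ``Eco1``).
    """

    genome_id: str
    replicons: list[Replicon] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)
    genetic_code: int = 11
    kingdom: str = "Bacteria"

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        ids = [r.id for r in self.replicons]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate replicon ids in genome {self.genome_id}")
        self.validate_features()

    def validate_features(self) -> None:
        by_id = {r.id: r for r in self.replicons}
        for f in self.features:
            rep = by_id.get(f.replicon_id)
            if rep is None:
                raise ValueError(
                    f"feature {f.id!r} references unknown replicon {f.replicon_id!r}"
                )
            limit = rep.length if rep.topology is Topology.linear else 2 * rep.length
            if f.end > limit:
                raise ValueError(
                    f"feature {f.id!r} out of bounds: end {f.end} > replicon "
                    f"{rep.id!r} length {rep.length}"
                )

    def replicon(self, rid: str) -> Replicon:
        for r in self.replicons:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def features_on(self, rid: str) -> list[GeneFeature]:
        return [f for f in self.features if f.replicon_id == rid]


@dataclass
class SeedGene:
    """A mapping seed: an integrase (IGE mode) or DDE transposase (IS mode)."""

    gene: GeneFeature
    mode: SeedMode = SeedMode.IGE

    def __post_init__(self) -> None:
        if self.mode is SeedMode.IGE and self.gene.klass not in INT_SEED_CLASSES:
            raise ValueError(
                f"IGE-mode seed requires an integrase class, got {self.gene.klass}"
            )
        if self.mode is SeedMode.IS and self.gene.klass is not GeneClass.DDE:
            raise ValueError("IS-mode seed requires a DDE transposase")

    @property
    def midpoint(self) -> int:
        return self.gene.midpoint


@dataclass
class HmmHit:
    subject_id: str
    pfam: str
    bitscore: float
    env_start: int = 1
    env_end: int = 1

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise ValueError(
                f"hit {self.subject_id}/{self.pfam}: env_start > env_end"
            )
        if not (self.bitscore == self.bitscore and abs(self.bitscore) != float("inf")):
            raise ValueError("bitscore must be finite")
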