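"""Deterministic synthetic genomes with planted integrative elements.

The generator emulates the comparative-genomic study conditions: a query
genome carrying planted elements (direct repeat duplicated at both
termini, integrase gene near one end), reference genomes in which the
integration site is uninterrupted (attB restored with a single DR copy),
references that still carry the element (which must contribute no
support), tandem arrays sharing recombinant att sites, transposed-IS
artifact pairs, and mock elements (random same-length segments of the
same replicon) as negative controls.

Direct repeats are native-site sequence: the DR content is the backbone
sequence at the integration point, so an element whose DR extends to the
end of an interrupted gene naturally restores that gene across attL —
exactly the restoring-fragment strategy of real elements.

Every output is a pure function of the spec and seed.  At each planted
junction the first/last interior bases are adjusted to differ from the
corresponding flanking bases, so that the true junction is the unique
maximal alignment boundary and planted coordinates are recovered
bit-exactly.

The deterministic internal alignment engine that backs these fixtures
lives in :mod:`tiger.engine` and is re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import KmerMatchEngine, revcomp  # noqa: F401  (fixture engine)
from .model import (
    GeneClass,
    GeneFeature,
    GenomeRecord,
    Replicon,
    Topology,
)

__all__ = [
    "IgeSpec", "RefSpec", "FixtureSpec", "Fixture", "TruthRow",
    "generate_fixture", "generate_mock_iges", "transposed_is_fixture",
    "synthetic_metric_vectors", "random_dna", "KmerMatchEngine",
]

BASES = "ACGT"

# one unambiguous codon per amino acid, for reverse-translating test domains
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def encode_peptide(pep: str) -> str:
    return "".join(CODON[a] for a in pep)


@dataclass
class IgeSpec:
    """One planted element.  Elements sharing ``attb_pos`` form a tandem
    array in specification order."""

    ige_id: str
    attb_pos: int           # 1-based backbone coordinate of the attB DR
    interior_len: int = 8_000
    dr_len: int = 45
    int_offset: int = 500   # integrase gene start within the interior
    int_len: int = 1_000
    int_klass: GeneClass = GeneClass.Y_INT
    target_klass: Optional[GeneClass] = None  # plant a target gene at attB
    target_name: str = ""


@dataclass
class RefSpec:
    """One reference genome: which planted elements it carries, and an
    i.i.d. substitution rate relative to the backbone."""

    ref_id: str
    include: frozenset[str] = frozenset()
    mutation_rate: float = 0.0


@dataclass
class TruthRow:
    ige_id: str
    left: int
    right: int
    dr_len: int
    seed_gene: str
    target: str = ""


@dataclass
class FixtureSpec:
    seed: int
    replicon_len: int = 60_000
    iges: list[IgeSpec] = field(default_factory=list)
    refs: list[RefSpec] = field(default_factory=list)
    n_clean_refs: int = 0       # shorthand: references with no elements
    n_same_ige_refs: int = 0    # references carrying every element
    circular: bool = False
    genome_id: str = "Syn1"
    #: (backbone position, dna) pairs overwriting backbone sequence, for
    #: planting genes with specific coding content (e.g. domain tests)
    backbone_inserts: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class Fixture:
    genome: GenomeRecord
    refs: dict[str, str]
    truth: list[TruthRow]
    backbone: str

    @property
    def replicon(self) -> Replicon:
        return self.genome.replicons[0]


def _distinct_base(rng: np.random.Generator, forbidden: set[str]) -> str:
    choices = [b for b in BASES if b not in forbidden]
    return str(rng.choice(choices))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        arr[i] = _distinct_base(rng, {arr[i]})
    return "".join(arr)


def _assemble(
    backbone: str,
    events: dict[int, list[tuple[IgeSpec, str]]],
    include: Optional[set[str]] = None,
) -> tuple[str, dict[str, tuple[int, int, int]]]:
    """Build a genome sequence by inserting (spec, interior) units at each
    attB position.  Returns the sequence and, per included element,
    (left, right, dr_len) in the built sequence's coordinates."""
    parts: list[str] = []
    coords: dict[str, tuple[int, int, int]] = {}
    prev = 1  # next backbone base to emit (1-based)
    pos = 0   # emitted length
    for p in sorted(events):
        units = [
            (s, interior) for s, interior in events[p]
            if include is None or s.ige_id in include
        ]
        if not units:
            continue
        dr = units[0][0].dr_len
        dr_seq = backbone[p - 1 : p - 1 + dr]
        parts.append(backbone[prev - 1 : p - 1 + dr])
        pos += (p - 1 + dr) - (prev - 1)
        start = pos - dr + 1  # coordinate of the attL DR start (or first
        # interior base when dr == 0)
        if dr == 0:
            start = pos + 1
        run = start
        for s, interior in units:
            parts.append(interior + dr_seq)
            pos += len(interior) + dr
            left = run
            right = left + dr + len(interior) + dr - 1
            if dr == 0:
                right = left + len(interior) - 1
            coords[s.ige_id] = (left, right, dr)
            run = right - dr + 1 if dr > 0 else right + 1
        prev = p + dr
    parts.append(backbone[prev - 1 :])
    return "".join(parts), coords


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate query genome, reference set and truth table from a spec."""
    rng = np.random.default_rng(spec.seed)
    backbone = list(random_dna(rng, spec.replicon_len))
    for pos, dna in spec.backbone_inserts:
        if pos < 1 or pos - 1 + len(dna) > spec.replicon_len:
            raise ValueError("backbone insert out of range")
        backbone[pos - 1 : pos - 1 + len(dna)] = list(dna)

    # group elements into events and materialize interiors
    events: dict[int, list[tuple[IgeSpec, str]]] = {}
    for s in spec.iges:
        if s.interior_len + 2 * s.dr_len > spec.replicon_len:
            raise ValueError(f"element {s.ige_id} larger than replicon")
        if not (1 <= s.attb_pos <= spec.replicon_len - s.dr_len):
            raise ValueError(f"element {s.ige_id}: attb_pos out of range")
        interior = list(random_dna(rng, s.interior_len))
        events.setdefault(s.attb_pos, []).append((s, interior))

    # junction disambiguation: at each event, the bases following the DR
    # (backbone and each interior prefix) must differ position-wise, and
    # likewise the bases preceding the DR (backbone and interior suffixes)
    for p, units in events.items():
        dr = units[0][0].dr_len
        for s, _ in units:
            if s.dr_len != dr:
                raise ValueError("tandem members must share dr_len")
        for i in range(4):
            after = {backbone[p - 1 + dr + i]}
            for _, interior in units:
                interior[i] = _distinct_base(rng, after)
                after.add(interior[i])
            before = {backbone[p - 2 - i]}
            for _, interior in units:
                interior[-1 - i] = _distinct_base(rng, before)
                before.add(interior[-1 - i])

    backbone_s = "".join(backbone)
    events_s = {
        p: [(s, "".join(i)) for s, i in units] for p, units in events.items()
    }
    all_ids = {s.ige_id for s in spec.iges}
    query_seq, coords = _assemble(backbone_s, events_s, all_ids)

    topo = Topology.circular if spec.circular else Topology.linear
    rep_id = f"{spec.genome_id}_rep1"
    features: list[GeneFeature] = []
    truth: list[TruthRow] = []
    for s in spec.iges:
        left, right, dr = coords[s.ige_id]
        int_start = left + dr + s.int_offset
        feat = GeneFeature(
            id=f"{s.ige_id}_int", replicon_id=rep_id,
            start=int_start, end=int_start + s.int_len - 1,
            strand="+", klass=s.int_klass,
        )
        features.append(feat)
        target = ""
        if s.target_klass is not None:
            # recombinant target gene spanning the attL DR block
            features.append(
                GeneFeature(
                    id=f"{s.ige_id}_target", replicon_id=rep_id,
                    start=max(1, left - 40), end=left + max(dr, 1) - 1,
                    strand="+", klass=s.target_klass, name=s.target_name,
                )
            )
            target = (
                f"{s.target_klass.value}-{s.target_name}"
                if s.target_name else s.target_klass.value
            )
        truth.append(
            TruthRow(
                ige_id=s.ige_id, left=left, right=right, dr_len=dr,
                seed_gene=feat.id, target=target,
            )
        )
    genome = GenomeRecord(
        genome_id=spec.genome_id,
        replicons=[Replicon(id=rep_id, seq=query_seq, topology=topo)],
        features=features,
    )

    refspecs = list(spec.refs)
    refspecs += [
        RefSpec(ref_id=f"clean{i + 1}") for i in range(spec.n_clean_refs)
    ]
    refspecs += [
        RefSpec(ref_id=f"carrier{i + 1}", include=frozenset(all_ids))
        for i in range(spec.n_same_ige_refs)
    ]
    refs: dict[str, str] = {}
    for rs in refspecs:
        seq, _ = _assemble(backbone_s, events_s, set(rs.include))
        refs[rs.ref_id] = _mutate(seq, rs.mutation_rate, rng)

    truth.sort(key=lambda t: t.left)
    return Fixture(genome=genome, refs=refs, truth=truth, backbone=backbone_s)


def generate_mock_iges(
    spans: Sequence[tuple[int, int]],
    replicon_len: int,
    k: int = 5,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Mock elements: for each real span, ``k`` random same-length segments
    of the same replicon, uniform start, avoiding the real spans."""
    rng = np.random.default_rng(seed)
    real = list(spans)
    mocks: list[tuple[int, int]] = []
    for left, right in real:
        size = right - left + 1
        made = 0
        while made < k:
            start = int(rng.integers(1, replicon_len - size + 2))
            end = start + size - 1
            if any(start <= r and l <= end for l, r in real):
                continue
            mocks.append((start, end))
            made += 1
    return mocks


def transposed_is_fixture(seed: int = 0) -> tuple[Fixture, dict[str, str]]:
    """The transposed-IS artifact scenario.

    The query replicon carries a 6-kb IS (with a DDE transposase gene)
    immediately left of a stranded integrase gene; no true element exists.
    One reference shares only the IS (transposed to an unrelated context)
    followed by a copy of the query's right flank, which makes the
    phase-I/II matches lie entirely within the IS and produces a spurious
    in-limits call when the IS filter is off.  A second reference has the
    IS locus uninterrupted, allowing IS-mode mapping to delineate the IS.
    Returns (fixture, is_db)."""
    rng = np.random.default_rng(seed)
    chrom_a = random_dna(rng, 20_000)
    is_dr = 8
    is_core = random_dna(rng, 6_000)
    pad_l = random_dna(rng, 700)
    int_gene = random_dna(rng, 1_000)
    pad_r = random_dna(rng, 900)
    chrom_b = random_dna(rng, 20_000)

    # IS integrates at the end of chrom_a with its own small DR
    dr_seq = chrom_a[-is_dr:]
    is_with_dr = is_core + dr_seq
    mid = pad_l + int_gene + pad_r

    def distinct(seq: str, other: str, head: bool) -> str:
        s = list(seq)
        for i in range(4):
            if head:
                s[i] = _distinct_base(rng, {other[i]})
            else:
                s[-1 - i] = _distinct_base(rng, {other[-1 - i]})
        return "".join(s)

    # unique junctions: IS interior vs the sequence at its uninterrupted site
    is_core = distinct(is_core, chrom_a[-is_dr - 4:] if is_dr >= 4 else mid, True)
    is_core = distinct(is_core, chrom_a[-4:], False)
    mid = distinct(mid, chrom_a[-4:] if is_dr == 0 else dr_seq[-4:], False)
    is_with_dr = is_core + dr_seq

    query = chrom_a + is_with_dr + mid + chrom_b
    is_left = len(chrom_a) - is_dr + 1
    is_right = len(chrom_a) + len(is_with_dr)

    # artifact reference: unrelated context + the IS + the query right flank
    artifact_ref = random_dna(rng, 5_000) + is_core + dr_seq + chrom_b[:10_000]
    # IS-clean reference: query with the IS excised (single DR copy)
    clean_is_ref = chrom_a + mid + chrom_b

    rep_id = "Art1_rep1"
    dde_start = is_left + is_dr + 2_000
    features = [
        GeneFeature(
            id="dde1", replicon_id=rep_id, start=dde_start,
            end=dde_start + 1_200, strand="+", klass=GeneClass.DDE,
        ),
        GeneFeature(
            id="int1", replicon_id=rep_id,
            start=is_right + len(pad_l) + 1,
            end=is_right + len(pad_l) + len(int_gene), strand="+",
            klass=GeneClass.Y_INT,
        ),
    ]
    genome = GenomeRecord(
        genome_id="Art1",
        replicons=[Replicon(id=rep_id, seq=query, topology=Topology.linear)],
        features=features,
    )
    fixture = Fixture(
        genome=genome,
        refs={"artifact": artifact_ref, "iscln": clean_is_ref},
        truth=[],  # no true element
        backbone=chrom_a + chrom_b,
    )
    is_db = {"IS_syn1": is_core + dr_seq}
    return fixture, is_db


def synthetic_metric_vectors(
    n: int = 400,
    seed: int = 0,
    separation: float = 3.0,
) -> tuple[list, list[bool], np.ndarray]:
    """Metric vectors with a planted linear separation.

    Baseline per-metric scales mimic genuine candidates (compositional
    biases of a few percent, enrichment differences of order one,
    lengths of 5–60 kb, integration-module distances of 1–5000 bp).
    Confirmed candidates are shifted by ``separation`` standard deviations
    along a fixed direction.  Returns (vectors, confirmed labels, the
    expected coefficient direction in raw-metric units)."""
    from .metrics import MetricVector

    rng = np.random.default_rng(seed)
    scales = np.array([0.03, 0.05, 0.5, 0.5, 0.15, 15_000.0, 1_500.0])
    means = np.array([0.05, 0.10, 0.0, 0.0, 0.0, 25_000.0, 2_500.0])
    w = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 0.3, -1.2])
    w = w / np.linalg.norm(w)

    labels = rng.random(n) < 0.5
    X = means + rng.normal(size=(n, 7)) * scales
    X[labels] += separation * (w * scales)
    # clamp to valid metric ranges
    X[:, 0] = np.clip(np.abs(X[:, 0]), 0, 1)
    X[:, 1] = np.clip(np.abs(X[:, 1]), 0, None)
    X[:, 5] = np.clip(X[:, 5], 2_000, 200_000)
    X[:, 6] = np.clip(X[:, 6], 1, None)
    vectors = [
        MetricVector(*[float(v) for v in row]) for row in X
    ]
    # logistic coefficients recover the discriminant direction w / scale
    expected = w / scales
    expected = expected / np.linalg.norm(expected)
    return vectors, [bool(b) for b in labels], expected


def disruption_fixture(
    seed: int = 0, restore: bool = False
) -> tuple[Fixture, str, dict[str, str]]:
    """An element integrated mid-domain of a planted protein gene.

    The gene encodes 40 pad residues, a 90-residue domain, 40 more pad
    residues; the crossover sits at domain residue 45.  With
    ``restore=False`` the DR length is zero, so the element truncates the
    domain at both attL and attR while the uninterrupted-site join
    restores it (expected outcome: attB wins — disruption without
    restoration).  With ``restore=True`` the DR extends from the crossover
    to the end of the gene, carrying the restoring gene fragment in attP,
    so the recombinant gene across attL is intact (expected: attLR wins).

    Returns (fixture, domain peptide, stub-scorer domain map)."""
    rng = np.random.default_rng(seed)
    aas = list(CODON)
    pad5 = "".join(rng.choice(aas, size=40))
    domain = "".join(rng.choice(aas, size=90))
    pad3 = "".join(rng.choice(aas, size=40))
    gene_dna = encode_peptide(pad5 + domain + pad3)
    gene_pos = 20_000
    crossover = gene_pos + 3 * (40 + 45)  # mid-domain, in-frame
    dr = 0 if not restore else (gene_pos + len(gene_dna) - crossover) + 9
    spec = FixtureSpec(
        seed=seed, replicon_len=60_000,
        iges=[IgeSpec("D", crossover, interior_len=8_000, dr_len=dr,
                      target_klass=GeneClass.CDS, target_name="tgt")],
        n_clean_refs=2,
        backbone_inserts=[(gene_pos, gene_dna)],
        genome_id="Dis1",
    )
    return generate_fixture(spec), domain, {"DOM_syn": domain}


def domain_genome(
    seed: int = 0, n_genes: int = 20, replicon_len: int = 60_000
) -> tuple[Replicon, dict[str, str]]:
    """A plain replicon carrying ``n_genes`` domain-encoding genes, for
    mock-element negative controls.  Returns (replicon, domain map)."""
    rng = np.random.default_rng(seed)
    seq = list(random_dna(rng, replicon_len))
    aas = list(CODON)
    domains: dict[str, str] = {}
    spacing = replicon_len // (n_genes + 1)
    for g in range(n_genes):
        pep = "".join(rng.choice(aas, size=90))
        name = f"DOM{g}"
        domains[name] = pep
        dna = encode_peptide(pep)
        pos = (g + 1) * spacing
        seq[pos - 1 : pos - 1 + len(dna)] = list(dna)
    return Replicon(id="mockrep", seq="".join(seq), topology=Topology.linear), domains
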