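"""Tandem building, overlap resolution, target assignment and naming.

Sequential integrations into recombinant att sites produce tandem arrays
of adjacent elements that share termini.  Raw calls are grouped into
tandems by exact terminus sharing, each tandem is partitioned at internal
termini into element units — every unit must contain an integrase gene and
respect the 2–200 kb size limits — and overlapping calls are resolved by
support, then by false-positive score.  Units implied by the partition but
lacking direct comparative-genomic support are emitted as inferred.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from Bio.Data.IUPACData import protein_letters_3to1

from .mapper import RawCall
from .model import GeneClass, GeneFeature, RNA_CLASSES

__all__ = [
    "IgeCall", "Tandem", "build_tandems", "resolve_tandem", "deoverlap",
    "resolve", "assign_target", "name_ige",
]

SIZE_LIMITS = (2_000, 200_000)


@dataclass
class IgeCall:
    """A resolved element unit."""

    replicon_id: str
    left: int
    right: int
    dr_len: int = 0
    support: int = 0
    seed_id: str = ""
    source: str = "tiger"           # tiger | islander | both
    inferred: bool = False
    fp: float = math.nan
    type: str = "Unknown"
    target: str = ""
    name: str = ""
    flags: set[str] = field(default_factory=set)
    raw: Optional[RawCall] = None

    @property
    def size(self) -> int:
        return self.right - self.left + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.left, self.right)

    def overlaps(self, other: "IgeCall") -> bool:
        return (
            self.replicon_id == other.replicon_id
            and self.left <= other.right
            and other.left <= self.right
        )

    @property
    def block_right(self) -> int:
        """Start coordinate of the right DR copy (right + 1 when dr = 0).

        Adjacent tandem units overlap by one DR copy, so terminus identity
        for tandem building uses DR-block starts: unit B follows unit A
        exactly when B.left == A.block_right."""
        return self.right - self.dr_len + 1 if self.dr_len > 0 else self.right + 1

    @property
    def terminus_keys(self) -> tuple[int, int]:
        return (self.left, self.block_right)

    def shares_terminus(self, other: "IgeCall") -> bool:
        return (
            self.left == other.block_right or other.left == self.block_right
        )

    def contains(self, other: "IgeCall") -> bool:
        """Strict containment: ``other`` lies inside with neither terminus
        shared (tandem members sharing a terminus are not nested)."""
        return (
            self.replicon_id == other.replicon_id
            and self.left < other.left
            and other.right < self.right
        )


@dataclass
class Tandem:
    """A group of calls connected by shared termini.

    ``termini`` holds the DR-block start keys in sorted order; ``dr_at``
    maps each key to the DR length observed there, so that the physical
    unit between consecutive keys ``a < b`` spans ``[a, b + dr_at[b] - 1]``
    (both DR copies included)."""

    replicon_id: str
    termini: list[int]
    calls: list[IgeCall]
    dr_at: dict[int, int] = field(default_factory=dict)
    units: list[IgeCall] = field(default_factory=list)


def _as_ige(call: RawCall, source: str = "tiger") -> IgeCall:
    return IgeCall(
        replicon_id=call.replicon_id, left=call.left, right=call.right,
        dr_len=call.dr_len, support=call.support,
        seed_id=call.seed.gene.id if call.seed else "",
        source=source, flags=set(call.flags), raw=call,
    )


def build_tandems(calls: Sequence[IgeCall]) -> list[Tandem]:
    """Group calls into tandems by the transitive closure of exact
    terminus sharing (coordinate fuzz is absorbed earlier, by variant
    merging)."""
    calls = list(calls)
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i], calls[j]
            if a.replicon_id != b.replicon_id:
                continue
            if set(a.terminus_keys) & set(b.terminus_keys):
                parent[find(i)] = find(j)
    groups: dict[int, list[IgeCall]] = {}
    for i, c in enumerate(calls):
        groups.setdefault(find(i), []).append(c)
    tandems = []
    for members in groups.values():
        termini = sorted({t for c in members for t in c.terminus_keys})
        dr_at: dict[int, int] = {}
        for c in members:
            for key in c.terminus_keys:
                dr_at[key] = max(dr_at.get(key, 0), c.dr_len)
        tandems.append(
            Tandem(replicon_id=members[0].replicon_id, termini=termini,
                   calls=sorted(members, key=lambda c: c.span), dr_at=dr_at)
        )
    tandems.sort(key=lambda t: (t.replicon_id, t.termini[0]))
    return tandems


def _unit_ok(
    left: int, right: int, int_features: Sequence[GeneFeature],
    size_limits: tuple[int, int],
) -> bool:
    if not (size_limits[0] <= right - left + 1 <= size_limits[1]):
        return False
    return any(f.overlaps(left, right) for f in int_features)


def resolve_tandem(
    t: Tandem,
    int_features: Sequence[GeneFeature],
    size_limits: tuple[int, int] = SIZE_LIMITS,
    max_enumeration: int = 16,
) -> list[IgeCall]:
    """Partition a tandem at internal termini into element units.

    Every unit must contain at least one integrase gene and obey the size
    limits.  Among valid partitions the one maximizing summed support of
    directly called units wins, ties broken by minimal summed
    false-positive score.  Units without a matching direct call are
    emitted with ``inferred=True``.  If no valid partition exists the
    best-supported single calls are returned, flagged unresolved."""
    term = t.termini
    by_key = {(c.left, c.block_right): c for c in t.calls}

    def unit_span(a: int, b: int) -> tuple[int, int]:
        dr = t.dr_at.get(b, 0)
        return a, b + dr - 1

    if len(term) == 2:
        only = by_key.get((term[0], term[1]))
        return [only] if only else []
    internal = term[1:-1]
    if len(internal) > max_enumeration:
        internal = internal[:max_enumeration]  # degenerate huge tandem
    best_units: Optional[list[IgeCall]] = None
    best_key: tuple[float, float] = (-1.0, float("inf"))
    for r in range(len(internal), -1, -1):
        for cuts in itertools.combinations(internal, r):
            bounds = [term[0], *cuts, term[-1]]
            units = []
            ok = True
            for a, b in zip(bounds, bounds[1:]):
                lo, hi = unit_span(a, b)
                if not _unit_ok(lo, hi, int_features, size_limits):
                    ok = False
                    break
                units.append((a, b))
            if not ok:
                continue
            supp = sum(by_key[u].support for u in units if u in by_key)
            fp = sum(
                by_key[u].fp for u in units
                if u in by_key and not math.isnan(by_key[u].fp)
            )
            key = (supp, -fp)
            if best_units is None or key > (best_key[0], -best_key[1]):
                best_key = (supp, fp)
                best_units = [
                    by_key[u] if u in by_key else IgeCall(
                        replicon_id=t.replicon_id,
                        left=unit_span(*u)[0], right=unit_span(*u)[1],
                        dr_len=t.dr_at.get(u[1], 0),
                        inferred=True, flags={"inferred"},
                    )
                    for u in units
                ]
    if best_units is None:
        out = []
        for c in sorted(t.calls, key=lambda c: -c.support):
            c.flags.add("unresolved_tandem")
            out.append(c)
        return out
    return best_units


def deoverlap(calls: Sequence[IgeCall]) -> list[IgeCall]:
    """Iteratively reject the worse member of each overlapping pair —
    lower support first, then higher false-positive score — until the set
    is overlap-free.  Tandem neighbours sharing a single terminus
    coordinate are not considered overlapping."""
    alive = list(calls)
    changed = True
    while changed:
        changed = False
        alive.sort(key=lambda c: (-c.support, c.fp if not math.isnan(c.fp) else 0.0))
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                a, b = alive[i], alive[j]
                if a.overlaps(b) and not a.shares_terminus(b):
                    # a precedes b in sort order, so b is the worse call
                    alive.pop(j)
                    changed = True
                    break
            if changed:
                break
    alive.sort(key=lambda c: (c.replicon_id, c.left))
    return alive


def _drop_nested(calls: list[IgeCall]) -> list[IgeCall]:
    """Disallow element-within-element raw configurations (inner dropped)."""
    return [
        c for c in calls
        if not any(other.contains(c) for other in calls)
    ]


def resolve(
    all_calls: Sequence[RawCall],
    islander_calls: Sequence[IgeCall] = (),
    mode: str = "tiger",
    int_features: Sequence[GeneFeature] = (),
    size_limits: tuple[int, int] = SIZE_LIMITS,
    fp_score_fn: Optional[Callable[[IgeCall], float]] = None,
    fp_cutoff: Optional[float] = None,
    rejected_seeds: Optional[set[str]] = None,
) -> list[IgeCall]:
    """Resolve raw calls into a final non-overlapping element set.

    Modes: ``islander`` (tRNA-site calls only), ``tiger`` (comparative-
    genomic calls only) or ``combined``.  In combined mode the tRNA-site
    call termini seed mixed tandems first — only comparative calls sharing
    one of those termini may join — then remaining calls form their own
    tandems.  Seed genes rejected by the support-ratio screen drop their
    dependent calls; nested configurations drop the inner call; the
    false-positive cutoff is applied last."""
    if mode not in ("islander", "tiger", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    rejected_seeds = rejected_seeds or set()
    tiger = [
        _as_ige(c) for c in all_calls
        if (c.seed.gene.id if c.seed else "") not in rejected_seeds
    ]
    isl = [c for c in islander_calls]
    for c in isl:
        c.source = "islander"
        if c.support == 0:
            c.support = 1  # pseudo-support for tRNA-site calls

    if fp_score_fn is not None:
        for c in tiger + isl:
            try:
                c.fp = fp_score_fn(c)
            except ValueError:
                pass

    units: list[IgeCall] = []
    if mode == "islander":
        pool = _drop_nested(isl)
        for t in build_tandems(pool):
            units.extend(resolve_tandem(t, int_features, size_limits))
    elif mode == "tiger":
        pool = _drop_nested(tiger)
        for t in build_tandems(pool):
            units.extend(resolve_tandem(t, int_features, size_limits))
    else:
        isl_termini = {x for c in isl for x in c.terminus_keys}
        mixed = list(isl)
        rest = []
        for c in tiger:
            if set(c.terminus_keys) & isl_termini:
                mixed.append(c)
            else:
                rest.append(c)
        # doubly-confirmed: identical spans from both methods collapse
        spans_isl = {c.span for c in isl}
        dedup_mixed: list[IgeCall] = []
        seen: dict[tuple[str, int, int], IgeCall] = {}
        for c in mixed:
            key = (c.replicon_id, *c.span)
            if key in seen:
                keep = seen[key]
                keep.source = "both"
                keep.flags.add("doubly_confirmed")
                keep.support = max(keep.support, c.support)
                if keep.raw is None:
                    keep.raw = c.raw
                    keep.dr_len = c.dr_len or keep.dr_len
                    keep.seed_id = keep.seed_id or c.seed_id
            else:
                seen[key] = c
                dedup_mixed.append(c)
        for c in dedup_mixed:
            if c.source == "tiger" and c.span in spans_isl:
                c.source = "both"
        pool = _drop_nested(dedup_mixed)
        for t in build_tandems(pool):
            units.extend(resolve_tandem(t, int_features, size_limits))
        rest = _drop_nested(rest)
        for t in build_tandems(rest):
            units.extend(resolve_tandem(t, int_features, size_limits))

    units = deoverlap(units)
    if fp_cutoff is not None:
        units = [
            u for u in units
            if math.isnan(u.fp) or u.fp < fp_cutoff
        ]
    return units


_TARGET_PRIORITY = [
    GeneClass.TRNA, GeneClass.TMRNA, GeneClass.OTHER_RNA, GeneClass.RRNA,
]


def assign_target(
    call: IgeCall,
    annotation: Sequence[GeneFeature],
    ref_annotation: Optional[Sequence[GeneFeature]] = None,
) -> str:
    """Type the attB site from the genes overlapping the direct-repeat
    block: 'multi-gene' when the DR overlaps two or more genes, else the
    class of the single overlapping gene, else 'intergenic'.  Reference-
    genome annotation is preferred when supplied; otherwise both DR copies
    on the query are consulted (attL first)."""
    dr = max(call.dr_len, 1)
    segments: list[tuple[Sequence[GeneFeature], int, int]] = []
    if ref_annotation:
        # reference coordinates: the attB context is centred on its DR
        segments.append((ref_annotation, call.left, call.left + dr - 1))
    feats = [f for f in annotation if f.replicon_id == call.replicon_id]
    segments.append((feats, call.left, call.left + dr - 1))
    segments.append((feats, call.right - dr + 1, call.right))
    best = "intergenic"
    for feat_set, lo, hi in segments:
        genes = [f for f in feat_set if f.overlaps(lo, hi)]
        if len(genes) >= 2:
            return "multi-gene"
        if len(genes) == 1:
            g = genes[0]
            if g.klass in RNA_CLASSES:
                label = g.klass.value
                return f"{label}-{g.name}" if g.name else label
            best = g.name or "CDS"
            return best
    return best


def name_ige(call: IgeCall, genome_id: str) -> str:
    """Element name GenomeID.Size.Target — size in kb, rounded; target
    abbreviated (one-letter amino acid for tRNA isotypes)."""
    kb = int(round(call.size / 1000.0))
    target = call.target or "u"
    if target.startswith("tRNA"):
        iso = target.split("-", 1)[1] if "-" in target else ""
        code = protein_letters_3to1.get(iso.capitalize(), iso or "t")
        target = code
    elif target == "tmRNA":
        target = "tmRNA"
    elif target == "intergenic":
        target = "ig"
    elif target == "multi-gene":
        target = "multi"
    return f"{genome_id}.{kb}.{target}"
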