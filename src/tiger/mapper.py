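"""Comparative-genomic "ping-pong" mapping of integrative elements.

The method rests on two principles: (i) the integration module of a mobile
element is cohesive, so an integrase (or transposase) gene marks the
vicinity of one element terminus; and (ii) the element occurs sporadically
among related genomes, so reference genomes exist in which its integration
site (attB) is uninterrupted.

From a seed gene midpoint, two 15-kb flank queries (q1L, q1R) probe a
reference collection.  A reference carrying the uninterrupted site yields a
phase-I match that truncates exactly at the junction between chromosomal
and element DNA, simultaneously locating the element's seed-proximal
terminus and the attB.  A 3-kb return query (q2) taken from the reference
just beyond that junction — reaching back 250 bp to span the direct-repeat
(DR) block — is aligned back to the source replicon; its match distal to
the seed locates the far terminus and the DR length.  The number of
distinct uninterrupted reference genomes supporting a call is its
comparative-genomic support.

IS mode uses a DDE transposase seed, a 30-bp reachback and 5–15 kb size
limits, and is used to reject the transposed-IS artifact, where a phase-I
or phase-II match lies entirely within a mobile IS rather than at a true
element junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .engine import AlignmentMatch, Engine, KmerMatchEngine, revcomp
from .model import (
    GeneClass,
    GenomeRecord,
    INT_SEED_CLASSES,
    Replicon,
    SeedGene,
    SeedMode,
    Topology,
)

log = logging.getLogger(__name__)

__all__ = ["MapperConfig", "Evidence", "RawCall", "take_flank_queries",
           "phase1_scan", "phase2_return", "locate_distal_end",
           "merge_variant_calls", "dedupe_sides", "is_artifact_filter",
           "map_seed", "map_genome"]


@dataclass
class MapperConfig:
    flank_len: int = 15_000
    q2_len: int = 3_000
    reachback: int = 250
    min_size: int = 2_000
    max_size: int = 200_000
    min_match: int = 500       # phase-I match length filter (exclusive)
    min_q2_match: int = 100    # phase-II match length floor
    min_distal_flank: int = 50 # distal match must extend this far past the DR
    proximal_tol: int = 10     # "reaches the input coordinate" slop
    merge_window: int = 20     # terminus fuzz absorbed by variant merging

    @classmethod
    def for_mode(cls, mode: SeedMode) -> "MapperConfig":
        if mode is SeedMode.IS:
            return cls(reachback=30, min_size=5_000, max_size=15_000)
        return cls()


@dataclass
class Evidence:
    """Per-reference support for one raw call."""

    ref_id: str
    q1_region: tuple[int, int]       # phase-I match span on the query replicon
    q2_region: tuple[int, int]       # phase-II distal match span on the replicon
    attB_context: str = ""           # uninterrupted site: 499 bp + DR + 499 bp
    attB_dr_len: int = 0
    truncated: bool = False


@dataclass
class RawCall:
    """A candidate element from one ping-pong round."""

    replicon_id: str
    left: int
    right: int
    dr_len: int
    seed: SeedGene
    side: str                        # "q1L" or "q1R"
    support: int = 1
    supporting_refs: list[str] = field(default_factory=list)
    evidence: list[Evidence] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return self.right - self.left + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.left, self.right)

    def overlaps(self, other: "RawCall") -> bool:
        return (
            self.replicon_id == other.replicon_id
            and self.left <= other.right
            and other.left <= self.right
        )

    @property
    def attB_context(self) -> str:
        return self.evidence[0].attB_context if self.evidence else ""


def take_flank_queries(
    seed: SeedGene, replicon: Replicon, flank_len: int = 15_000
) -> tuple[tuple[str, int], tuple[str, int]]:
    """Return ((q1L, startL), (q1R, startR)): the flank sequences and the
    replicon coordinate of each window's first base (may be <1 on a
    circular replicon, indicating an origin wrap)."""
    mid = seed.midpoint
    n = replicon.length
    if n < 2_000:
        raise ValueError(f"replicon {replicon.id} shorter than 2 kb")
    if replicon.topology is Topology.circular:
        l_start, l_end = mid - flank_len, mid - 1
        r_start, r_end = mid + 1, mid + flank_len
        # never wrap all the way around
        span = min(flank_len, n - 1)
        l_start = mid - span
        r_end = mid + span
    else:
        l_start, l_end = max(1, mid - flank_len), mid - 1
        r_start, r_end = mid + 1, min(n, mid + flank_len)
    q1L = replicon.fetch(l_start, l_end) if l_end >= l_start else ""
    q1R = replicon.fetch(r_start, r_end) if r_end >= r_start else ""
    return (q1L, l_start), (q1R, r_start)


def phase1_scan(
    q1: str,
    refdb: Mapping[str, str],
    side: str,
    engine: Engine,
    config: MapperConfig,
) -> dict[str, AlignmentMatch]:
    """Probe the reference collection with one flank query.

    Keeps matches longer than ``min_match`` whose query-side alignment does
    *not* reach the coordinate-proximal end of the query (a match that does
    indicates a reference containing the same element).  At most one match
    — the best-scoring — is retained per reference.
    """
    matches = engine.search(q1, refdb, query_id=side)
    best: dict[str, AlignmentMatch] = {}
    for m in matches:
        if m.length <= config.min_match:
            continue
        if side == "q1L":
            if m.q_end >= len(q1) - config.proximal_tol:
                continue  # reference contains the same element
        else:
            if m.q_start <= 1 + config.proximal_tol:
                continue
        cur = best.get(m.subject_id)
        if cur is None or m.score > cur.score:
            best[m.subject_id] = m
    return best


def _orient(match: AlignmentMatch, ref_seq: str) -> tuple[AlignmentMatch, str]:
    """Normalize a match to the + strand by reverse-complementing the
    reference when needed; coordinates are remapped accordingly."""
    if match.strand == "+":
        return match, ref_seq
    n = len(ref_seq)
    return (
        replace(
            match,
            s_start=n - match.s_end + 1,
            s_end=n - match.s_start + 1,
            strand="+",
        ),
        revcomp(ref_seq),
    )


def phase2_return(
    match: AlignmentMatch,
    ref_seq: str,
    side: str,
    config: MapperConfig,
) -> Optional[tuple[str, int, bool]]:
    """Build the return query from the reference region adjacent to the
    coordinate-proximal end of the phase-I match, reaching back
    ``config.reachback`` bp into the matched region to span the DR.

    Returns (q2, rb_used, truncated) or None if the region is unusable.
    ``rb_used`` is the realized reachback after boundary truncation.
    """
    n = len(ref_seq)
    rb, q2l = config.reachback, config.q2_len
    if side == "q1L":
        start = match.s_end - rb + 1
        end = match.s_end - rb + q2l
        lo, hi = max(1, start), min(n, end)
        rb_used = match.s_end - lo + 1
    else:
        start = match.s_start + rb - q2l
        end = match.s_start + rb - 1
        lo, hi = max(1, start), min(n, end)
        rb_used = hi - match.s_start + 1
    if hi - lo + 1 < rb + config.min_distal_flank:
        return None
    truncated = (lo != start) or (hi != end)
    rb_used = min(rb_used, rb)
    return ref_seq[lo - 1 : hi], rb_used, truncated


def locate_distal_end(
    q2_matches: Sequence[AlignmentMatch],
    q2_len: int,
    rb_used: int,
    junction: int,
    seed: SeedGene,
    side: str,
    config: MapperConfig,
) -> Optional[tuple[int, int, int, tuple[int, int], set[str]]]:
    """Fix the seed-distal terminus from the q2-vs-replicon matches.

    Combines the phase-I junction with the distal q2 match: the offset of
    the match start within the reachback region gives the DR length, and
    (left, right) termini follow.  Returns
    (left, right, dr_len, distal_span, flags) or None if no distal match
    yields an in-limits element.
    """
    mid = seed.midpoint
    candidates: list[tuple[int, int, int, tuple[int, int]]] = []
    for m in q2_matches:
        if m.strand != "+" or m.length < config.min_q2_match:
            continue
        if side == "q1L":
            if m.s_start <= mid:
                continue  # not distal to the seed
            dr = rb_used - m.q_start + 1
            if not (0 <= dr <= rb_used):
                continue
            if m.q_end < rb_used + config.min_distal_flank:
                continue  # DR-only match, no flank beyond it
            left = junction - dr + 1
            right = m.s_start + dr - 1
        else:
            if m.s_end >= mid:
                continue
            flank = q2_len - rb_used
            dr = m.q_end - flank
            if not (0 <= dr <= rb_used):
                continue
            if m.q_start > flank - config.min_distal_flank:
                continue
            right = junction + dr - 1
            left = m.s_end - dr + 1
        if config.min_size <= right - left + 1 <= config.max_size:
            candidates.append((left, right, dr, (m.s_start, m.s_end)))
    if not candidates:
        return None
    flags: set[str] = set()
    if len(candidates) > 1:
        flags.add("ambiguous_distal")
    # conservative: the smallest in-limits element
    left, right, dr, span = min(candidates, key=lambda c: c[1] - c[0])
    return left, right, dr, span, flags


def merge_variant_calls(calls: list[RawCall], window: int = 20) -> list[RawCall]:
    """Merge calls whose two termini each differ by <= ``window`` bp
    (transitive closure).  The merged call takes the coordinates of the
    best-supported member and the summed support of all members."""
    if not calls:
        return []
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
            if (
                a.replicon_id == b.replicon_id
                and abs(a.left - b.left) <= window
                and abs(a.right - b.right) <= window
            ):
                parent[find(i)] = find(j)
    groups: dict[int, list[RawCall]] = {}
    for i, c in enumerate(calls):
        groups.setdefault(find(i), []).append(c)
    out = []
    for members in groups.values():
        best = max(members, key=lambda c: (c.support, -c.left))
        refs: list[str] = []
        evidence: list[Evidence] = []
        flags: set[str] = set()
        for m in members:
            refs.extend(r for r in m.supporting_refs if r not in refs)
            evidence.extend(m.evidence)
            flags |= m.flags
        out.append(
            replace(
                best,
                support=sum(m.support for m in members),
                supporting_refs=refs,
                evidence=evidence,
                flags=flags,
            )
        )
    out.sort(key=lambda c: (c.replicon_id, c.left, c.right))
    return out


def dedupe_sides(calls: list[RawCall]) -> list[RawCall]:
    """Collapse identical-coordinate calls arising from both q1L and q1R
    (short elements are seen from both flanks).  Support counts distinct
    supporting references, never doubled."""
    by_span: dict[tuple[str, int, int], RawCall] = {}
    for c in calls:
        key = (c.replicon_id, c.left, c.right)
        cur = by_span.get(key)
        if cur is None:
            by_span[key] = replace(
                c,
                supporting_refs=list(c.supporting_refs),
                evidence=list(c.evidence),
                flags=set(c.flags),
            )
        else:
            for r, ev in zip(c.supporting_refs, c.evidence):
                if r not in cur.supporting_refs:
                    cur.supporting_refs.append(r)
                    cur.evidence.append(ev)
            cur.flags |= c.flags
            cur.support = len(cur.supporting_refs)
    out = list(by_span.values())
    for c in out:
        c.support = len(c.supporting_refs) or c.support
    out.sort(key=lambda c: (c.replicon_id, c.left, c.right))
    return out


def _region_in_is(
    region: tuple[int, int],
    replicon: Replicon,
    genome: GenomeRecord,
    refdb: Mapping[str, str],
    engine: Engine,
    is_db: Optional[Mapping[str, str]],
    slop: int = 10,
) -> bool:
    """True when ``region`` of the replicon lies entirely within a mobile IS.

    First maps candidate ISs by running the engine in IS mode from any DDE
    transposase gene within the region; failing that, searches the region
    against an IS sequence database.  Partial coverage never rejects."""
    lo, hi = region
    dde = [
        f for f in genome.features_on(replicon.id)
        if f.klass is GeneClass.DDE and f.overlaps(lo, hi)
    ]
    for gene in dde:
        seed = SeedGene(gene=gene, mode=SeedMode.IS)
        try:
            is_calls = map_seed(
                seed, genome, refdb, MapperConfig.for_mode(SeedMode.IS),
                engine=engine, is_filter=False,
            )
        except ValueError:
            continue
        for c in is_calls:
            if c.left - slop <= lo and hi <= c.right + slop:
                return True
    if is_db:
        seq = replicon.fetch(lo, hi)
        for m in engine.search(seq, is_db, query_id="is_check"):
            if m.q_start <= 1 + slop and m.q_end >= len(seq) - slop:
                return True
    return False


def is_artifact_filter(
    call: RawCall,
    genome: GenomeRecord,
    refdb: Mapping[str, str],
    engine: Engine,
    is_db: Optional[Mapping[str, str]] = None,
) -> str:
    """Verdict ('keep' or 'reject') for the transposed-IS artifact.

    A call is rejected when, for every piece of supporting evidence, the
    phase-I or phase-II match region lies entirely within an IS (as mapped
    by IS-mode ping-pong from a contained DDE gene, or as covered by an IS
    database record).  Evidence that fails the test is discarded; the call
    survives with reduced support if any clean evidence remains."""
    replicon = genome.replicon(call.replicon_id)
    clean_refs, clean_ev = [], []
    for ref, ev in zip(call.supporting_refs, call.evidence):
        tainted = _region_in_is(
            ev.q1_region, replicon, genome, refdb, engine, is_db
        ) or _region_in_is(ev.q2_region, replicon, genome, refdb, engine, is_db)
        if not tainted:
            clean_refs.append(ref)
            clean_ev.append(ev)
    if not clean_refs:
        return "reject"
    call.supporting_refs = clean_refs
    call.evidence = clean_ev
    call.support = len(clean_refs)
    return "keep"


def map_seed(
    seed: SeedGene,
    genome: GenomeRecord,
    refdb: Mapping[str, str],
    config: Optional[MapperConfig] = None,
    engine: Optional[Engine] = None,
    is_filter: bool = True,
    is_db: Optional[Mapping[str, str]] = None,
) -> list[RawCall]:
    """Run the full ping-pong round for one seed gene.

    Returns merged, side-deduplicated raw calls; support equals the number
    of distinct uninterrupted reference genomes yielding each call."""
    config = config or MapperConfig.for_mode(seed.mode)
    engine = engine or KmerMatchEngine()
    replicon = genome.replicon(seed.gene.replicon_id)
    if replicon.length < 2_000:
        log.warning("replicon %s shorter than 2 kb; seed %s skipped",
                    replicon.id, seed.gene.id)
        return []
    (q1L, startL), (q1R, startR) = take_flank_queries(
        seed, replicon, config.flank_len
    )
    per_side: dict[str, list[RawCall]] = {"q1L": [], "q1R": []}
    for side, q1, q_start in (("q1L", q1L, startL), ("q1R", q1R, startR)):
        if len(q1) <= config.min_match:
            continue
        hits = phase1_scan(q1, refdb, side, engine, config)
        for ref_id, match in hits.items():
            match, ref_seq = _orient(match, refdb[ref_id])
            built = phase2_return(match, ref_seq, side, config)
            if built is None:
                continue
            q2, rb_used, truncated = built
            junction = (
                q_start + match.q_end - 1 if side == "q1L"
                else q_start + match.q_start - 1
            )
            q2_matches = engine.search(
                q2, {replicon.id: replicon.seq}, query_id="q2"
            )
            located = locate_distal_end(
                q2_matches, len(q2), rb_used, junction, seed, side, config
            )
            if located is None:
                continue
            left, right, dr, distal_span, flags = located
            if side == "q1L":
                q1_region = (q_start + match.q_start - 1, junction)
                ctx_lo = match.s_end - dr + 1 - 499
                ctx_hi = match.s_end + 499
            else:
                q1_region = (junction, q_start + match.q_end - 1)
                ctx_lo = match.s_start - 499
                ctx_hi = match.s_start + dr - 1 + 499
            ctx = ref_seq[max(0, ctx_lo - 1) : min(len(ref_seq), ctx_hi)]
            if truncated:
                flags = flags | {"q2_truncated"}
            per_side[side].append(
                RawCall(
                    replicon_id=replicon.id, left=left, right=right,
                    dr_len=dr, seed=seed, side=side, support=1,
                    supporting_refs=[ref_id],
                    evidence=[Evidence(
                        ref_id=ref_id, q1_region=q1_region,
                        q2_region=distal_span, attB_context=ctx,
                        attB_dr_len=dr, truncated=truncated,
                    )],
                    flags=flags,
                )
            )
    if is_filter:
        for side in per_side:
            per_side[side] = [
                c for c in per_side[side]
                if is_artifact_filter(c, genome, refdb, engine, is_db) == "keep"
            ]
    merged = []
    for side in ("q1L", "q1R"):
        merged.extend(merge_variant_calls(per_side[side], config.merge_window))
    return dedupe_sides(merged)


def map_genome(
    genome: GenomeRecord,
    refdb: Mapping[str, str],
    mode: SeedMode = SeedMode.IGE,
    config: Optional[MapperConfig] = None,
    engine: Optional[Engine] = None,
    is_db: Optional[Mapping[str, str]] = None,
    is_filter: bool = True,
) -> list[RawCall]:
    """Map every eligible seed gene in the genome."""
    engine = engine or KmerMatchEngine()
    wanted = INT_SEED_CLASSES if mode is SeedMode.IGE else {GeneClass.DDE}
    calls: list[RawCall] = []
    for f in genome.features:
        if f.klass not in wanted:
            continue
        seed = SeedGene(gene=f, mode=mode)
        calls.extend(
            map_seed(
                seed, genome, refdb,
                config or MapperConfig.for_mode(mode),
                engine=engine, is_filter=is_filter, is_db=is_db,
            )
        )
    return calls
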