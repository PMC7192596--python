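"""Integrase-tree analytics: clade statistics, promiscuity screening,
IS607-style profile classification, and detection of regulated gene
integrity (RGI) candidates.

A site-promiscuous integrase clade is shallow (little protein divergence)
yet uses diverse attB sites; candidates are screened in clade depth (mean
pairwise patristic distance) versus site-usage purity, anchored by the
known promiscuous IS607 clade.  RGI candidates are tight, high-support
clades in which two or more deduplicated elements disrupt the same protein
domain at the same position — the signature of repeated, regulatory
gene-inactivating integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy

from .classify import DisruptionResult, Outcome
from .hmm import HmmScorer

__all__ = [
    "CladeStats", "RgiCandidate", "clade_stats", "promiscuity_screen",
    "classify_is607", "detect_rgi", "chi2_2x2",
]


@dataclass
class CladeStats:
    node_id: str
    members: list[str]
    support: float           # bootstrap fraction in [0, 1]
    depth: float             # mean pairwise patristic distance
    top_site: str = ""
    purity: float = 0.0      # percent of members using the top site
    flags: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)


def _parse_support(label: Optional[str]) -> float:
    """Bootstrap support from a node label; percent vs fraction is
    auto-detected (values > 1 are percentages)."""
    if label is None or label == "":
        return 0.0
    try:
        v = float(label)
    except ValueError:
        return 0.0
    return v / 100.0 if v > 1.0 else v


def load_tree(source: str) -> dendropy.Tree:
    """Read a newick tree from a path or a literal newick string."""
    if source.strip().startswith("("):
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def clade_stats(
    tree: dendropy.Tree | str,
    site_map: Mapping[str, str],
) -> list[CladeStats]:
    """Per internal node: members, bootstrap support, depth and site purity.

    Depth is the mean pairwise leaf-to-leaf path length within the clade
    (invariant under rerooting).  Leaves missing from ``site_map`` are
    excluded from purity with a flag."""
    if isinstance(tree, str):
        tree = load_tree(tree)
    pdm = tree.phylogenetic_distance_matrix()
    out: list[CladeStats] = []
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        leaves = [lf.taxon for lf in node.leaf_iter()]
        if len(leaves) < 2:
            continue
        counter += 1
        names = [t.label for t in leaves]
        total, npairs = 0.0, 0
        for i in range(len(leaves)):
            for j in range(i + 1, len(leaves)):
                total += pdm.patristic_distance(leaves[i], leaves[j])
                npairs += 1
        depth = total / npairs
        flags: set[str] = set()
        sites = []
        for n in names:
            s = site_map.get(n)
            if s is None:
                flags.add("missing_site")
            else:
                sites.append(s)
        if sites:
            top_site = max(sorted(set(sites)), key=sites.count)
            purity = 100.0 * sites.count(top_site) / len(sites)
        else:
            top_site, purity = "", 0.0
        out.append(
            CladeStats(
                node_id=node.label or f"node{counter}",
                members=names,
                support=_parse_support(node.label),
                depth=depth, top_site=top_site, purity=purity, flags=flags,
            )
        )
    return out


def promiscuity_screen(
    clades: Sequence[CladeStats],
    is607_depth: float,
    purity_max: float = 25.0,
    support_min: float = 0.5,
    min_size: int = 5,
) -> list[CladeStats]:
    """Flag candidate promiscuous clades: high support, site purity below
    ``purity_max`` percent and depth not exceeding the IS607 anchor depth.
    Clades of four or fewer members are excluded (their minimum possible
    purity is already 25%)."""
    return [
        c for c in clades
        if c.size >= min_size
        and c.support >= support_min
        and c.purity < purity_max
        and c.depth <= is607_depth
    ]


def classify_is607(
    int_seq: str, scorer: HmmScorer, cutoff: float = 64.0
) -> bool:
    """IS607-family membership by profile score at the calibrated cutoff
    (64 bits collects exactly the phylogenetic clade)."""
    hits = scorer.score(int_seq, subject_id="int")
    return bool(hits) and max(h.bitscore for h in hits) >= cutoff


@dataclass
class RgiCandidate:
    clade: CladeStats
    disrupted_pfam: str
    positions: list[int]

    @property
    def n_independent(self) -> int:
        return len(self.clade.members)


def detect_rgi(
    clades: Sequence[CladeStats],
    disruptions: Mapping[str, DisruptionResult],
    pos_tol: int = 10,
    depth_cutoff: float = 0.5,
    support_min: float = 0.5,
) -> list[RgiCandidate]:
    """Regulated-gene-integrity candidates: tight (depth <= cutoff),
    high-support clades of two or more deduplicated elements, all
    disrupting the same domain without restoration, at crossover positions
    within ``pos_tol`` residues of one another.  Nested candidates
    collapse to the largest qualifying clade."""
    candidates: list[RgiCandidate] = []
    for c in clades:
        if c.size < 2 or c.support < support_min or c.depth > depth_cutoff:
            continue
        results = [disruptions.get(m) for m in c.members]
        if any(r is None or r.outcome is not Outcome.attB_win for r in results):
            continue
        pfams = {r.best_pfam for r in results}
        if len(pfams) != 1:
            continue
        positions = [r.crossover_pos_in_domain for r in results]
        if max(positions) - min(positions) > pos_tol:
            continue
        candidates.append(
            RgiCandidate(clade=c, disrupted_pfam=pfams.pop(), positions=positions)
        )
    # keep only maximal clades
    keep = []
    for c in candidates:
        mem = set(c.clade.members)
        if not any(
            mem < set(o.clade.members) for o in candidates if o is not c
        ):
            keep.append(c)
    return keep


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]] without
    continuity correction, df = 1."""
    from scipy.stats import chi2_contingency

    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("chi2_2x2: zero marginal total")
    stat, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
    return float(stat), float(p)
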