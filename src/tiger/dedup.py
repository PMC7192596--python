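"""Deduplication of vertically inherited near-identical elements.

Closely related source genomes can carry the same element from a single
ancestral integration event; such copies would bias clade-level analyses.
Pairwise fragment-based average nucleotide identity (ANI) is computed
between elements; pairs with ANI > 0.95 and aligned fraction > 0.9 form a
unit-weight similarity graph, all-pairs shortest paths (Floyd–Warshall)
feed DBSCAN with eps=1 and min_samples=2 — which on a unit-weight graph is
exactly connected components — and each cluster is replaced by a single
representative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = ["AniEdge", "pairwise_ani", "build_edges", "cluster_iges",
           "choose_representative", "deduplicate"]

ANI_MIN = 0.95
AF_MIN = 0.9


@dataclass
class AniEdge:
    ige_a: str
    ige_b: str
    ani: float
    af: float

    def __post_init__(self) -> None:
        if not (0 <= self.ani <= 1 and 0 <= self.af <= 1):
            raise ValueError("ani and af must lie in [0, 1]")


def _map_fragment(frag: str, target: str, min_identity: float = 0.8) -> Optional[float]:
    """Best infix alignment identity of a fragment within the target, or
    None when no placement reaches the admission identity."""
    import edlib

    res = edlib.align(frag, target, mode="HW", task="distance")
    dist = res["editDistance"]
    if dist < 0:
        return None
    ident = 1.0 - dist / len(frag)
    return ident if ident >= min_identity else None


def pairwise_ani(
    a: str, b: str, frag_len: int = 500, min_frag: int = 2,
    min_identity: float = 0.8,
) -> Optional[tuple[float, float]]:
    """Fragment-based one-directional ANI of ``a`` against ``b``.

    ``a`` is cut into non-overlapping ``frag_len``-bp fragments; each is
    placed at its best local match in ``b``.  ANI is the mean identity of
    the mapped fragments and AF the mapped fraction of fragments; fewer
    than ``min_frag`` mapped fragments yields no estimate."""
    if len(a) < frag_len * min_frag:
        return None
    n_frags = len(a) // frag_len
    idents = []
    for i in range(n_frags):
        frag = a[i * frag_len : (i + 1) * frag_len]
        ident = _map_fragment(frag, b, min_identity)
        if ident is not None:
            idents.append(ident)
    if len(idents) < min_frag:
        return None
    return float(np.mean(idents)), len(idents) / n_frags


def build_edges(
    seqs: Mapping[str, str],
    frag_len: int = 500,
    min_frag: int = 2,
    ani_min: float = ANI_MIN,
    af_min: float = AF_MIN,
) -> list[AniEdge]:
    """All-pairs filtered ANI edges.  Both directions are computed and the
    pair is kept when either direction passes the thresholds."""
    ids = list(seqs)
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            for qa, qb in ((a, b), (b, a)):
                r = pairwise_ani(seqs[qa], seqs[qb], frag_len, min_frag)
                if r is not None and r[0] > ani_min and r[1] > af_min:
                    edges.append(AniEdge(ige_a=a, ige_b=b, ani=r[0], af=r[1]))
                    break
    return edges


def cluster_iges(
    edges: Sequence[AniEdge], ids: Sequence[str]
) -> list[list[str]]:
    """Cluster elements on the filtered similarity graph.

    Unit edge weights; Floyd–Warshall all-pairs shortest paths; DBSCAN on
    the distance matrix with eps=1, min_samples=2.  Singleton elements
    remain unclustered (no cluster of size 1 is emitted)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import floyd_warshall
    from sklearn.cluster import DBSCAN

    ids = list(ids)
    if not edges:
        return []
    index = {x: i for i, x in enumerate(ids)}
    n = len(ids)
    rows, cols = [], []
    for e in edges:
        i, j = index[e.ige_a], index[e.ige_b]
        rows += [i, j]
        cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = floyd_warshall(graph, directed=False, unweighted=True)
    big = n + 1.0
    dist[~np.isfinite(dist)] = big
    labels = DBSCAN(eps=1, min_samples=2, metric="precomputed").fit_predict(dist)
    clusters: dict[int, list[str]] = {}
    for x, lab in zip(ids, labels):
        if lab >= 0:
            clusters.setdefault(lab, []).append(x)
    return [sorted(v) for _, v in sorted(clusters.items())]


def choose_representative(
    cluster: Sequence[str],
    support: Optional[Mapping[str, int]] = None,
    fp: Optional[Mapping[str, float]] = None,
) -> str:
    """Deterministic representative: highest support, then lowest (best)
    false-positive score, then lexicographically first id."""
    support = support or {}
    fp = fp or {}
    return min(
        cluster,
        key=lambda x: (-support.get(x, 0), fp.get(x, 0.0), x),
    )


def deduplicate(
    seqs: Mapping[str, str],
    support: Optional[Mapping[str, int]] = None,
    fp: Optional[Mapping[str, float]] = None,
    frag_len: int = 500,
    min_frag: int = 2,
) -> tuple[list[str], list[list[str]]]:
    """Full pipeline: edges, clusters, representatives.

    Returns (kept ids, clusters); kept = singletons plus one
    representative per cluster, in input order."""
    edges = build_edges(seqs, frag_len=frag_len, min_frag=min_frag)
    clusters = cluster_iges(edges, list(seqs))
    drop: set[str] = set()
    for cl in clusters:
        rep = choose_representative(cl, support, fp)
        drop |= set(cl) - {rep}
    kept = [x for x in seqs if x not in drop]
    return kept, clusters
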