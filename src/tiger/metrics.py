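"""False-positive metrics and the trainable false-positive score.

Seven per-candidate metrics separate real integrated elements from false
calls: two compositional (mononucleotide and dinucleotide bias relative to
the host replicon), three gene-content based (housekeeping-domain
enrichment, foreign-domain enrichment, fraction of hypothetical proteins),
the element length, and delta-int — the distance from the nearest contained
integrase gene to an element terminus, a direct measure of integration-
module cohesion.

A false-positive score is trained from these metrics: candidates are
standardized, projected onto principal components, a convex hull is drawn
in the (PC1, PC3) plane around independently confirmed elements, within-
hull membership labels the training data, and a logistic-link linear model
on the raw metrics yields the score.  Higher scores indicate likely false
positives.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, Delaunay

from .engine import revcomp
from .model import GeneClass, GeneFeature, RNA_CLASSES

__all__ = [
    "MetricVector", "FpModel", "mono_bias", "dinuc_bias",
    "gene_content_metrics", "delta_int", "build_enrichment_table",
    "train_fp_model", "fp_score", "support_ratio_filter",
]

METRIC_NAMES = (
    "mono_bias", "dinuc_bias", "housekeeping", "foreignness",
    "hypothetical", "length", "delta_int",
)


@dataclass
class MetricVector:
    mono_bias: float
    dinuc_bias: float
    housekeeping: float
    foreignness: float
    hypothetical: float
    length: float
    delta_int: float
    flags: set[str] = field(default_factory=set)

    def as_array(self) -> np.ndarray:
        a = np.array(
            [getattr(self, n) for n in METRIC_NAMES], dtype=float
        )
        if not np.all(np.isfinite(a)):
            raise ValueError("metric vector contains non-finite values")
        return a


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / acgt


def mono_bias(ige_seq: str, replicon_seq: str) -> float:
    """Absolute difference of G+C content between element and replicon."""
    return abs(_gc_fraction(ige_seq.upper()) - _gc_fraction(replicon_seq.upper()))


def _dinuc_rho(seq: str) -> dict[str, float]:
    """Dinucleotide relative abundances rho*_XY = f_XY / (f_X f_Y) computed
    on the sequence concatenated with its reverse complement (the standard
    strand-symmetrized genomic-signature convention)."""
    both = [seq, revcomp(seq)]
    mono: dict[str, int] = {b: 0 for b in "ACGT"}
    di: dict[str, int] = {}
    n_mono = n_di = 0
    for s in both:
        for b in s:
            if b in mono:
                mono[b] += 1
                n_mono += 1
        for i in range(len(s) - 1):
            d = s[i : i + 2]
            if d[0] in "ACGT" and d[1] in "ACGT":
                di[d] = di.get(d, 0) + 1
                n_di += 1
    if n_di == 0:
        raise ValueError("sequence too short for dinucleotide counting")
    fm = {b: c / n_mono for b, c in mono.items()}
    rho = {}
    for x in "ACGT":
        for y in "ACGT":
            denom = fm[x] * fm[y]
            if denom == 0:
                continue  # degenerate composition; term skipped
            rho[x + y] = (di.get(x + y, 0) / n_di) / denom
    return rho


def dinuc_bias(ige_seq: str, replicon_seq: str) -> float:
    """Karlin dinucleotide signature difference:
    delta* = (1/16) sum_XY | rho*_XY(element) - rho*_XY(replicon) |."""
    ra = _dinuc_rho(ige_seq.upper())
    rb = _dinuc_rho(replicon_seq.upper())
    keys = ra.keys() & rb.keys()
    return sum(abs(ra[k] - rb[k]) for k in keys) / 16.0


EnrichmentTable = Mapping[str, float]


def build_enrichment_table(
    positive_genes: Sequence[GeneFeature], all_genes: Sequence[GeneFeature]
) -> dict[str, float]:
    """Per-Pfam enrichment factor: count among positive-set genes divided
    by count among all genes.  Pfams unseen in the full gene set are
    excluded; Pfams absent from the positives score 0."""
    all_counts: dict[str, int] = {}
    for g in all_genes:
        if g.top_pfam:
            all_counts[g.top_pfam[0]] = all_counts.get(g.top_pfam[0], 0) + 1
    pos_counts: dict[str, int] = {}
    for g in positive_genes:
        if g.top_pfam:
            pos_counts[g.top_pfam[0]] = pos_counts.get(g.top_pfam[0], 0) + 1
    return {
        pfam: pos_counts.get(pfam, 0) / total
        for pfam, total in all_counts.items()
    }


def _protein_genes(genes: Iterable[GeneFeature]) -> list[GeneFeature]:
    return [g for g in genes if g.klass not in RNA_CLASSES]


def gene_content_metrics(
    ige_genes: Sequence[GeneFeature],
    replicon_genes: Sequence[GeneFeature],
    hk_table: EnrichmentTable,
    fg_table: EnrichmentTable,
) -> tuple[float, float, float, set[str]]:
    """(housekeeping, foreignness, hypothetical) for one candidate.

    The first two are the mean enrichment factor over the candidate's
    Pfam-called protein genes minus the same mean over all protein genes of
    its replicon; hypothetical is the difference in the fraction of protein
    genes lacking any Pfam call."""
    flags: set[str] = set()

    def mean_enrich(genes: Sequence[GeneFeature], table: EnrichmentTable) -> Optional[float]:
        vals = [table.get(g.top_pfam[0], 0.0) for g in genes if g.top_pfam]
        return sum(vals) / len(vals) if vals else None

    def hypo_frac(genes: Sequence[GeneFeature]) -> float:
        prots = _protein_genes(genes)
        if not prots:
            return 0.0
        return sum(1 for g in prots if not g.top_pfam) / len(prots)

    ige_p, rep_p = _protein_genes(ige_genes), _protein_genes(replicon_genes)
    hk = fg = None
    hk_i, hk_r = mean_enrich(ige_p, hk_table), mean_enrich(rep_p, hk_table)
    fg_i, fg_r = mean_enrich(ige_p, fg_table), mean_enrich(rep_p, fg_table)
    if hk_i is None or hk_r is None:
        flags.add("no_pfam_genes")
        hk = 0.0
    else:
        hk = hk_i - hk_r
    if fg_i is None or fg_r is None:
        flags.add("no_pfam_genes")
        fg = 0.0
    else:
        fg = fg_i - fg_r
    hyp = hypo_frac(ige_p) - hypo_frac(rep_p)
    return hk, fg, hyp, flags


def delta_int(
    ige: tuple[int, int], int_genes: Sequence[GeneFeature]
) -> int:
    """Shortest distance (bp, floored at 1) between a contained integrase
    gene and an element terminus; 1 when an integrase overhangs a terminus."""
    left, right = ige
    inside = [g for g in int_genes if g.overlaps(left, right)]
    if not inside:
        raise ValueError("delta_int: no integrase gene overlaps the element")
    best = None
    for g in inside:
        if g.start < left or g.end > right:
            d = 1
        else:
            d = max(1, min(g.start - left, right - g.end))
        best = d if best is None else min(best, d)
    return best


@dataclass
class FpModel:
    """Linear false-positive score: score = intercept + coef . metrics.

    Higher scores indicate false positives; a candidate passes when its
    score falls below ``cutoff``.  The PCA basis used for hull labelling is
    retained for provenance/serialization."""

    coefficients: np.ndarray
    intercept: float
    cutoff: float
    auroc: float = float("nan")
    scaler_mean: Optional[np.ndarray] = None
    scaler_scale: Optional[np.ndarray] = None
    pca_components: Optional[np.ndarray] = None

    def to_json(self, path: os.PathLike | str) -> None:
        obj = {
            "coefficients": list(map(float, self.coefficients)),
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "auroc": self.auroc,
            "metric_names": list(METRIC_NAMES),
            "scaler_mean": None if self.scaler_mean is None else list(map(float, self.scaler_mean)),
            "scaler_scale": None if self.scaler_scale is None else list(map(float, self.scaler_scale)),
            "pca_components": None if self.pca_components is None else [
                list(map(float, row)) for row in self.pca_components
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path: os.PathLike | str) -> "FpModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            coefficients=np.asarray(obj["coefficients"], dtype=float),
            intercept=float(obj["intercept"]),
            cutoff=float(obj["cutoff"]),
            auroc=float(obj.get("auroc", float("nan"))),
            scaler_mean=None if obj.get("scaler_mean") is None else np.asarray(obj["scaler_mean"]),
            scaler_scale=None if obj.get("scaler_scale") is None else np.asarray(obj["scaler_scale"]),
            pca_components=None if obj.get("pca_components") is None else np.asarray(obj["pca_components"]),
        )


def train_fp_model(
    labeled: Sequence[tuple[MetricVector, bool]],
    train_frac: float = 0.75,
    seed: int = 0,
    hull_plane: tuple[int, int] = (0, 2),
) -> FpModel:
    """Train the false-positive score.

    ``labeled`` pairs each metric vector with whether the candidate was
    independently confirmed.  Standardized metrics are projected on
    principal components; a convex hull around the confirmed points in the
    ``hull_plane`` (default PC1 vs PC3) relabels candidates as within-hull
    (true) or outside-hull (false); a logistic-link linear model on the raw
    metrics is fit on a random ``train_frac`` of the data, and AUROC is
    evaluated on the remainder."""
    from sklearn.decomposition import PCA
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.preprocessing import StandardScaler

    if len(labeled) < 50:
        raise ValueError("need at least 50 labeled vectors")
    X = np.vstack([v.as_array() for v, _ in labeled])
    confirmed = np.array([c for _, c in labeled], dtype=bool)
    if confirmed.all() or not confirmed.any():
        raise ValueError("need both confirmed and unconfirmed candidates")

    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    n_comp = max(hull_plane) + 1
    pca = PCA(n_components=max(n_comp, 3), random_state=seed).fit(Z)
    P = pca.transform(Z)[:, list(hull_plane)]

    pts = P[confirmed]
    if len(pts) < 3:
        raise ValueError("degenerate hull: fewer than 3 confirmed points")
    hull = ConvexHull(pts)
    tri = Delaunay(pts[hull.vertices])
    inside = tri.find_simplex(P) >= 0
    y = ~inside  # 1 = false positive

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(X))
    n_train = int(round(train_frac * len(X)))
    tr, te = idx[:n_train], idx[n_train:]
    if y[tr].all() or not y[tr].any():
        raise ValueError("training split has a single class; reseed")

    clf = LogisticRegression(C=np.inf, max_iter=5000)  # unregularized
    clf.fit(X[tr], y[tr])
    scores_te = clf.decision_function(X[te])
    auroc = float(roc_auc_score(y[te], scores_te)) if len(set(y[te])) > 1 else float("nan")

    # cutoff: maximize Youden's J on the training scores
    scores_tr = clf.decision_function(X[tr])
    order = np.argsort(scores_tr)
    s_sorted, y_sorted = scores_tr[order], y[tr][order]
    n_pos, n_neg = y_sorted.sum(), (~y_sorted).sum()
    best_j, best_cut = -1.0, float(np.median(s_sorted))
    for i in range(1, len(s_sorted)):
        cut = (s_sorted[i - 1] + s_sorted[i]) / 2
        tpr = (y_sorted[i:].sum()) / n_pos
        fpr = ((~y_sorted[i:]).sum()) / n_neg
        j = tpr - fpr
        if j > best_j:
            best_j, best_cut = j, cut
    return FpModel(
        coefficients=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        cutoff=float(best_cut),
        auroc=auroc,
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        pca_components=pca.components_.copy(),
    )


def fp_score(v: MetricVector, model: FpModel) -> tuple[float, bool]:
    """Linear false-positive score and pass verdict (pass = below cutoff)."""
    x = v.as_array()
    score = float(model.intercept + model.coefficients @ x)
    if math.isnan(score):
        raise ValueError("fp_score: missing or invalid metric")
    return score, score < model.cutoff


def support_ratio_filter(
    int_calls: Mapping[str, Sequence],
    ratio_cutoff: float = 4.0,
    overlap_cutoff: int = 5,
) -> set[str]:
    """Reject seed genes whose call signal indicates recombination activity
    not due to the candidate integrase.

    For each seed with two or more mutually overlapping raw calls, the
    top:second-best support ratio and the overlap count are examined; a
    seed is rejected when the overlap count reaches ``overlap_cutoff`` and
    the ratio falls below ``ratio_cutoff``.  Returns the rejected seed ids."""
    rejected: set[str] = set()
    for seed_id, calls in int_calls.items():
        if len(calls) < 2:
            continue
        top = max(calls, key=lambda c: c.support)
        overlapping = [c for c in calls if c.overlaps(top)]
        if len(overlapping) < 2:
            continue
        supports = sorted((c.support for c in overlapping), reverse=True)
        ratio = supports[0] / max(supports[1], 1)
        if len(overlapping) >= overlap_cutoff and ratio < ratio_cutoff:
            rejected.add(seed_id)
    return rejected
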